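"""Individual-based forest demography on a patch mosaic.

Stand dynamics emerge from birth, growth and death of individual trees
competing for light in 20x20 m patches (default 5x5 grid = 1 ha, torus
boundary).  Each patch is divided into 0.5 m height layers where the leaf
area of resident crowns accumulates; irradiance declines downward by a
light extinction law.  A tree's gross production integrates a saturating
single-leaf light response analytically over its own leaf area index
(self-shading); maintenance and growth respiration are subtracted, and
the net biomass increment is inverted through the allometry to update
dbh, height, crown and leaf area.  Mortality combines a background rate,
an elevated rate for slow-growing trees, crowding-driven self-thinning
(crown areas may not exceed the patch area), and gap formation by large
falling trees that damage a neighboring patch.  Recruitment enters at
dbh = 1 cm at a species maximum rate reduced linearly by shading.

Tree state is stored in flat numpy arrays (struct-of-arrays) so annual
steps over thousands of trees stay fast; a ``Tree`` record view is
provided for inspection.

The shipped species table (data/species_demo.tsv) is an illustrative,
synthetic three-species parameterization with plausible magnitudes for an
evergreen temperate rainforest; it is not a published calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesParams", "SpeciesTable", "Tree", "Stand",
    "light_profile", "leaf_photosynthesis", "tree_gross_production",
    "annual_production_gco2", "load_species_table",
    "PATCH_SIDE_M", "PATCH_AREA_M2", "LAYER_HEIGHT_M",
    "CO2_G_PER_UMOL", "CO2_PER_C",
]

PATCH_SIDE_M = 20.0
PATCH_AREA_M2 = 400.0
LAYER_HEIGHT_M = 0.5

#: grams per umol CO2
CO2_G_PER_UMOL = 44.01e-6
#: g CO2 per g C (molar mass ratio)
CO2_PER_C = 44.01 / 12.01

#: stand-level light extinction coefficient used for the patch profile
STAND_K = 0.5

# gap formation: dying trees at least this dbh (cm) may fall and damage a
# neighboring patch, with this probability
FALLING_MIN_DBH = 45.0
FALLING_PROB = 0.3

#: recruits enter at this stem diameter (cm)
RECRUIT_DBH = 1.0

_SPECIES_COLUMNS = [
    "species_id", "pmax", "alpha_light", "light_extinction_k",
    "leaf_transmittance_m", "resp_maintenance", "resp_growth",
    "h_max", "h_half", "cd_per_dbh", "crown_length_frac", "crown_lai",
    "form_factor", "wood_density", "max_dbh",
    "mort_background", "mort_slow", "slow_growth_dbh",
    "max_recruits", "light_threshold",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic/physiological parameters of one species.

    pmax: maximum leaf photosynthetic rate (umol CO2 m-2 s-1);
    alpha_light: initial slope of the light response (umol CO2 per umol
    photons); light_extinction_k and leaf_transmittance_m shape the
    within-crown light profile.  Respiration: resp_maintenance is the
    fraction of biomass respired per year, resp_growth the fraction of net
    assimilate spent on growth respiration.  Allometry: height saturates
    as h_max*dbh/(dbh+h_half); crown diameter is cd_per_dbh*dbh (m per
    cm); leaf area is crown_lai per unit crown area; above-ground biomass
    is stem volume x form_factor x wood_density x carbon fraction 0.5.
    Mortality: background rate plus mort_slow when the annual dbh
    increment falls below slow_growth_dbh (cm yr-1).  Recruitment:
    max_recruits per patch per year at full light, reduced linearly below
    light_threshold (fraction of above-canopy light at the floor).
    """

    species_id: str
    pmax: float
    alpha_light: float
    light_extinction_k: float
    leaf_transmittance_m: float
    resp_maintenance: float
    resp_growth: float
    h_max: float
    h_half: float
    cd_per_dbh: float
    crown_length_frac: float
    crown_lai: float
    form_factor: float
    wood_density: float
    max_dbh: float
    mort_background: float
    mort_slow: float
    slow_growth_dbh: float
    max_recruits: float
    light_threshold: float

    def __post_init__(self) -> None:
        for name in ("pmax", "alpha_light", "light_extinction_k", "h_max",
                     "h_half", "cd_per_dbh", "crown_lai", "form_factor",
                     "wood_density", "slow_growth_dbh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.species_id}: {name} must be >= 0")
        for name in ("mort_background", "mort_slow", "leaf_transmittance_m",
                     "resp_growth", "crown_length_frac", "light_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{self.species_id}: {name} must be in [0, 1]")
        if self.max_dbh <= 1.0:
            raise ValueError(f"{self.species_id}: max_dbh must exceed 1 cm")
        if self.max_recruits < 0:
            raise ValueError(f"{self.species_id}: max_recruits must be >= 0")


class SpeciesTable:
    """Indexed species set with parameter arrays for vectorized demography."""

    def __init__(self, species: Sequence[SpeciesParams]) -> None:
        if not species:
            raise ValueError("species table is empty")
        self.species = list(species)
        self.ids = [sp.species_id for sp in species]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate species_id")
        for col in _SPECIES_COLUMNS[1:]:
            setattr(self, col,
                    np.array([getattr(sp, col) for sp in species], dtype=float))

    def __len__(self) -> int:
        return len(self.species)

    def index(self, species_id: str) -> int:
        return self.ids.index(species_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(sp) for sp in self.species])


def load_species_table(path: str | Path) -> SpeciesTable:
    """Read a tab-separated species parameter file (one row per species)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"species file {path}: missing columns {sorted(missing)}")
    return SpeciesTable([
        SpeciesParams(**{c: row[c] for c in _SPECIES_COLUMNS})
        for _, row in df.iterrows()
    ])


# ---------------------------------------------------------------------------
# allometry (vectorized over trees; sp_* are per-tree parameter arrays)


def allometric_height(dbh: np.ndarray, h_max: np.ndarray,
                      h_half: np.ndarray) -> np.ndarray:
    """Tree height (m), saturating in dbh (cm)."""
    return h_max * dbh / (dbh + h_half)


def allometric_crown_area(dbh: np.ndarray, cd_per_dbh: np.ndarray) -> np.ndarray:
    """Crown projection area (m2) from crown diameter proportional to dbh."""
    return math.pi / 4.0 * (cd_per_dbh * dbh) ** 2


def allometric_biomass(dbh: np.ndarray, h_max: np.ndarray, h_half: np.ndarray,
                       form_factor: np.ndarray,
                       wood_density: np.ndarray) -> np.ndarray:
    """Above-ground biomass (tC): stem volume x form factor x density x 0.5."""
    basal = math.pi / 4.0 * (np.asarray(dbh) / 100.0) ** 2    # m2
    height = allometric_height(np.asarray(dbh), h_max, h_half)
    return basal * height * form_factor * wood_density * 0.5


def dbh_from_biomass(biomass: np.ndarray, dbh_guess: np.ndarray,
                     h_max: np.ndarray, h_half: np.ndarray,
                     form_factor: np.ndarray, wood_density: np.ndarray,
                     tol: float = 1e-10, max_iter: int = 40) -> np.ndarray:
    """Invert the biomass allometry for dbh by safeguarded Newton iteration.

    B(d) = c*d^3/(d + h_half) is smooth and strictly increasing, so Newton
    from the previous dbh converges in a handful of iterations; iterates
    are clipped to stay positive.
    """
    c = math.pi / 8.0 * 1e-4 * form_factor * wood_density * h_max
    d = np.maximum(np.asarray(dbh_guess, dtype=float).copy(), 1e-3)
    b = np.asarray(biomass, dtype=float)
    for _ in range(max_iter):
        f = c * d ** 3 / (d + h_half) - b
        df = c * d ** 2 * (2.0 * d + 3.0 * h_half) / (d + h_half) ** 2
        step = f / df
        d_new = np.clip(d - step, 0.5 * d, 2.0 * d)
        if np.all(np.abs(d_new - d) <= tol * np.maximum(d, 1.0)):
            d = d_new
            break
        d = d_new
    else:
        resid = np.abs(c * d ** 3 / (d + h_half) - b)
        if np.any(resid > 1e-6 * np.maximum(b, 1e-12)):
            raise RuntimeError("allometry inversion failed to converge")
    return d


# ---------------------------------------------------------------------------
# light & photosynthesis


def light_profile(leaf_area_per_layer: np.ndarray, k: float = STAND_K,
                  above_canopy_light: float = 1.0) -> np.ndarray:
    """Irradiance at the *top* of each height layer (top layer first = index -1).

    Layer ell receives above_canopy_light * exp(-k * cumulative LAI above
    ell); layers are ordered bottom-up (index 0 = lowest), matching the
    stand profile arrays.  Non-increasing downward.
    """
    la = np.asarray(leaf_area_per_layer, dtype=float)
    lai_above = np.cumsum(la[::-1])[::-1] - la  # exclusive of own layer
    return above_canopy_light * np.exp(-k * lai_above)


def leaf_photosynthesis(irradiance: np.ndarray | float, pmax: float,
                        alpha: float, k: float, m: float) -> np.ndarray | float:
    """Saturating single-leaf light response used inside the canopy integral.

    P(I) = pmax * a*k*I / (a*k*I + pmax*(1-m)) in umol CO2 m-2 s-1, where
    a*k*I is the photon flux absorbed per unit leaf area at transmittance m.
    """
    u = alpha * k * np.asarray(irradiance, dtype=float)
    out = pmax * u / (u + pmax * (1.0 - m))
    return float(out) if np.ndim(out) == 0 else out


def tree_gross_production(incident_light: np.ndarray | float,
                          tree_lai: np.ndarray | float,
                          pmax: np.ndarray | float, alpha: np.ndarray | float,
                          k: np.ndarray | float, m: np.ndarray | float,
                          ) -> np.ndarray | float:
    """Canopy photosynthesis per unit crown area (umol CO2 m-2 s-1).

    Analytic integral of the single-leaf response over the tree's own leaf
    area index L with within-crown extinction k:

        (pmax/k) * ln[(a k I + c) / (a k I e^{-kL} + c)],  c = pmax (1-m).

    Non-negative, increasing and saturating in light; per unit LAI it
    recovers the single-leaf rate as L -> 0.
    """
    i0 = np.asarray(incident_light, dtype=float)
    lai = np.asarray(tree_lai, dtype=float)
    u = alpha * k * i0
    c = pmax * (1.0 - m)
    out = pmax / k * np.log((u + c) / (u * np.exp(-k * lai) + c))
    return float(out) if out.ndim == 0 else out


def annual_production_gco2(rate_umol_m2_s: np.ndarray | float,
                           crown_area: np.ndarray | float,
                           active_seconds: float) -> np.ndarray | float:
    """Scale a crown-area photosynthetic rate to g CO2 per year per tree."""
    return rate_umol_m2_s * crown_area * active_seconds * CO2_G_PER_UMOL


# ---------------------------------------------------------------------------
# the stand


@dataclass
class Tree:
    """Record view of one tree (for inspection and inventory I/O)."""

    species_id: str
    dbh: float
    height: float
    crown_area: float
    leaf_area: float
    biomass: float
    patch_index: int


class Stand:
    """A mosaic of 20x20 m patches holding individual trees.

    Tree state lives in flat arrays (`dbh`, `species` index, `patch`
    index); geometry and biomass are derived from dbh through the species
    allometry on demand.
    """

    def __init__(self, species_table: SpeciesTable, nx: int = 5, ny: int = 5,
                 mean_daylight_s: float = 12.0 * 3600.0) -> None:
        self.sp = species_table
        self.nx, self.ny = int(nx), int(ny)
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must be at least 1x1")
        self.n_patches = self.nx * self.ny
        self.area_m2 = self.n_patches * PATCH_AREA_M2
        self.mean_daylight_s = mean_daylight_s
        self.dbh = np.empty(0, dtype=float)
        self.species = np.empty(0, dtype=np.int64)
        self.patch = np.empty(0, dtype=np.int64)
        self.last_increment = np.empty(0, dtype=float)

    # -- construction ---------------------------------------------------

    @classmethod
    def bare_ground(cls, species_table: SpeciesTable, nx: int = 5,
                    ny: int = 5) -> "Stand":
        """Treeless stand (succession starts from recruitment)."""
        return cls(species_table, nx, ny)

    @classmethod
    def from_inventory(cls, species_table: SpeciesTable,
                       inventory: pd.DataFrame, nx: int = 5, ny: int = 5,
                       rng: np.random.Generator | None = None) -> "Stand":
        """Initialize from a (species_id, dbh_cm[, patch_index]) table.

        Trees without a patch index are assigned round-robin so the
        inventory spreads evenly over the mosaic.
        """
        stand = cls(species_table, nx, ny)
        n = len(inventory)
        sp_idx = np.array([species_table.index(s)
                           for s in inventory["species_id"]], dtype=np.int64)
        if "patch_index" in inventory.columns and inventory["patch_index"].notna().all():
            patch = inventory["patch_index"].to_numpy(dtype=np.int64)
            if np.any((patch < 0) | (patch >= stand.n_patches)):
                raise ValueError("patch_index out of range for the grid")
        else:
            patch = np.arange(n, dtype=np.int64) % stand.n_patches
        stand.dbh = inventory["dbh_cm"].to_numpy(dtype=float).copy()
        if np.any(stand.dbh < RECRUIT_DBH):
            raise ValueError("inventory dbh below the 1 cm recruitment threshold")
        stand.species = sp_idx
        stand.patch = patch
        stand.last_increment = np.full(n, np.inf)  # no slow-growth penalty yet
        return stand

    # -- derived per-tree arrays ----------------------------------------

    def _sp(self, name: str) -> np.ndarray:
        return getattr(self.sp, name)[self.species]

    @property
    def n_trees(self) -> int:
        return self.dbh.size

    def height(self) -> np.ndarray:
        return allometric_height(self.dbh, self._sp("h_max"), self._sp("h_half"))

    def crown_area(self) -> np.ndarray:
        return allometric_crown_area(self.dbh, self._sp("cd_per_dbh"))

    def leaf_area(self) -> np.ndarray:
        return self.crown_area() * self._sp("crown_lai")

    def biomass(self) -> np.ndarray:
        return allometric_biomass(self.dbh, self._sp("h_max"),
                                  self._sp("h_half"), self._sp("form_factor"),
                                  self._sp("wood_density"))

    def trees(self) -> list[Tree]:
        h = self.height()
        ca = self.crown_area()
        la = self.leaf_area()
        b = self.biomass()
        return [Tree(self.sp.ids[self.species[i]], self.dbh[i], h[i], ca[i],
                     la[i], b[i], int(self.patch[i]))
                for i in range(self.n_trees)]

    # -- aggregates ------------------------------------------------------

    def stand_lai(self) -> float:
        """Stand leaf area index (m2 leaf per m2 ground)."""
        return float(self.leaf_area().sum() / self.area_m2)

    def basal_area(self) -> float:
        """Basal area in m2 ha-1."""
        ha = self.area_m2 / 1e4
        return float(np.sum(math.pi * (self.dbh / 200.0) ** 2) / ha)

    def agb(self) -> float:
        """Above-ground biomass in tC ha-1."""
        return float(self.biomass().sum() / (self.area_m2 / 1e4))

    def metrics(self, dbh_edges: Iterable[float] = (1, 5, 15, 25, 35, 45, 55,
                                                    65, 75, 85, 95, 105, 200),
                ) -> dict:
        """Stand structure summary: basal area, AGB, LAI, dbh histogram."""
        counts, edges = np.histogram(self.dbh, bins=np.asarray(list(dbh_edges)))
        return {
            "n_trees": self.n_trees,
            "basal_area_m2_ha": self.basal_area(),
            "agb_tc_ha": self.agb(),
            "stand_lai": self.stand_lai(),
            "dbh_class_edges": edges,
            "dbh_class_counts": counts,
        }

    # -- light ------------------------------------------------------------

    def leaf_area_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-patch per-layer leaf area, per-tree top-layer index).

        Each crown's leaf area is spread uniformly over its 0.5 m layers
        between crown base (height*(1-crown_length_frac)) and the tree top.
        Layers are ordered bottom-up.
        """
        h = self.height()
        top = np.ceil(h / LAYER_HEIGHT_M).astype(np.int64)
        n_layers = int(top.max()) + 1 if self.n_trees else 1
        bot = np.floor(h * (1.0 - self._sp("crown_length_frac"))
                       / LAYER_HEIGHT_M).astype(np.int64)
        top = np.maximum(top, bot + 1)
        la = self.leaf_area()
        per_layer = la / (top - bot)
        # difference-array trick: add at bottom, subtract above top, cumsum
        prof = np.zeros((self.n_patches, n_layers + 1))
        np.add.at(prof, (self.patch, bot), per_layer)
        np.add.at(prof, (self.patch, top), -per_layer)
        prof = np.cumsum(prof, axis=1)[:, :-1]
        return prof, np.minimum(top, n_layers - 1)

    def light_at_crown_top(self, k: float = STAND_K) -> np.ndarray:
        """Fraction of above-canopy light at each tree's crown top."""
        if self.n_trees == 0:
            return np.empty(0)
        prof, top = self.leaf_area_profile()
        lai_layer = prof / PATCH_AREA_M2
        # cumulative LAI strictly above each layer (bottom-up ordering)
        above = np.cumsum(lai_layer[:, ::-1], axis=1)[:, ::-1] - lai_layer
        frac = np.exp(-k * above)
        return frac[self.patch, top]

    def floor_light(self, k: float = STAND_K) -> np.ndarray:
        """Per-patch light fraction reaching the forest floor."""
        lai_patch = np.bincount(self.patch, weights=self.leaf_area(),
                                minlength=self.n_patches) / PATCH_AREA_M2
        return np.exp(-k * lai_patch)

    # -- production -------------------------------------------------------

    def potential_production(self, mean_light: float,
                             active_days: int = 365) -> np.ndarray:
        """Potential annual gross production per tree (g CO2 yr-1).

        mean_light is the mean daytime photon flux above the canopy
        (umol m-2 s-1); each tree sees it attenuated to its crown top and
        integrates its leaf response over its own LAI.
        """
        if self.n_trees == 0:
            return np.empty(0)
        incident = self.light_at_crown_top() * mean_light
        rate = tree_gross_production(
            incident, self._sp("crown_lai"), self._sp("pmax"),
            self._sp("alpha_light"), self._sp("light_extinction_k"),
            self._sp("leaf_transmittance_m"))
        active_seconds = active_days * self.mean_daylight_s
        return annual_production_gco2(rate, self.crown_area(), active_seconds)

    # -- annual demographic step -----------------------------------------

    def grow(self, pb_gco2: np.ndarray, omega_year: float) -> None:
        """Update biomass/dbh from realized production pb * omega_year.

        Biomass increment = (1 - growth respiration) * (size-limited gross
        production - maintenance respiration); floored at zero (trees do
        not shrink).  dbh, height and crown follow by inverse allometry.
        """
        if not 0.0 <= omega_year <= 1.0:
            raise ValueError("omega_year must be in [0, 1]")
        if self.n_trees == 0:
            self.last_increment = np.empty(0)
            return
        pb_tc = np.asarray(pb_gco2) * omega_year / CO2_PER_C * 1e-6
        size_limit = np.clip(1.0 - (self.dbh / self._sp("max_dbh")) ** 2,
                             0.0, 1.0)
        b = self.biomass()
        db = (1.0 - self._sp("resp_growth")) \
            * (pb_tc * size_limit - self._sp("resp_maintenance") * b)
        db = np.maximum(db, 0.0)
        new_dbh = dbh_from_biomass(b + db, self.dbh, self._sp("h_max"),
                                   self._sp("h_half"), self._sp("form_factor"),
                                   self._sp("wood_density"))
        self.last_increment = new_dbh - self.dbh
        self.dbh = new_dbh

    def apply_mortality(self, rng: np.random.Generator) -> int:
        """Stochastic deaths + gap formation + self-thinning; returns removals."""
        if self.n_trees == 0:
            return 0
        p = self._sp("mort_background") \
            + self._sp("mort_slow") * (self.last_increment
                                       < self._sp("slow_growth_dbh"))
        dead = rng.random(self.n_trees) < np.clip(p, 0.0, 1.0)

        # large dying trees may fall onto one of the four torus neighbors,
        # killing trees there with probability proportional to crown overlap
        fallers = np.flatnonzero(dead & (self.dbh >= FALLING_MIN_DBH))
        if fallers.size:
            falls = fallers[rng.random(fallers.size) < FALLING_PROB]
            crown = self.crown_area()
            for i in falls:
                target = self._neighbor_patch(int(self.patch[i]),
                                              int(rng.integers(4)))
                victims = np.flatnonzero((self.patch == target) & ~dead)
                if victims.size:
                    p_dmg = min(1.0, crown[i] / PATCH_AREA_M2)
                    dead[victims[rng.random(victims.size) < p_dmg]] = True

        removed = int(dead.sum())
        self._keep(~dead)
        removed += self.self_thin()
        return removed

    def _neighbor_patch(self, patch: int, direction: int) -> int:
        x, y = patch % self.nx, patch // self.nx
        dx, dy = ((1, 0), (-1, 0), (0, 1), (0, -1))[direction]
        return (x + dx) % self.nx + ((y + dy) % self.ny) * self.nx

    def self_thin(self) -> int:
        """Enforce the crown-area constraint: remove smallest trees first
        in any patch whose summed crown area exceeds the patch area."""
        if self.n_trees == 0:
            return 0
        crown = self.crown_area()
        totals = np.bincount(self.patch, weights=crown,
                             minlength=self.n_patches)
        crowded = np.flatnonzero(totals > PATCH_AREA_M2)
        if not crowded.size:
            return 0
        keep = np.ones(self.n_trees, dtype=bool)
        for pi in crowded:
            idx = np.flatnonzero(self.patch == pi)
            order = idx[np.argsort(self.dbh[idx])]  # smallest first
            excess = totals[pi] - PATCH_AREA_M2
            for i in order:
                if excess <= 0:
                    break
                keep[i] = False
                excess -= crown[i]
        removed = int((~keep).sum())
        self._keep(keep)
        return removed

    def apply_recruitment(self, rng: np.random.Generator,
                          floor_light: np.ndarray | None = None) -> int:
        """Poisson recruitment at dbh = 1 cm, shading-reduced; returns count.

        Expected recruits per patch and species = max_recruits * f, with
        f = 1 at floor light >= the species threshold and declining
        linearly to 0 at darkness.
        """
        if floor_light is None:
            floor_light = self.floor_light()
        floor_light = np.asarray(floor_light, dtype=float)
        if np.any((floor_light < 0) | (floor_light > 1)):
            raise ValueError("floor light fractions must be in [0, 1]")
        thr = self.sp.light_threshold[None, :]
        f = np.clip(floor_light[:, None] / np.where(thr > 0, thr, 1.0), 0, 1)
        f = np.where(thr > 0, f, 1.0)
        counts = rng.poisson(self.sp.max_recruits[None, :] * f)
        total = int(counts.sum())
        if total:
            patch_idx, sp_idx = np.nonzero(counts)
            reps = counts[patch_idx, sp_idx]
            self.dbh = np.concatenate([self.dbh, np.full(total, RECRUIT_DBH)])
            self.species = np.concatenate([self.species,
                                           np.repeat(sp_idx, reps)])
            self.patch = np.concatenate([self.patch,
                                         np.repeat(patch_idx, reps)])
            self.last_increment = np.concatenate(
                [self.last_increment, np.full(total, np.inf)])
        return total

    def step_year(self, pb_gco2: np.ndarray, omega_year: float,
                  rng: np.random.Generator) -> None:
        """One annual demographic step: growth, mortality, recruitment."""
        self.grow(pb_gco2, omega_year)
        self.apply_mortality(rng)
        self.apply_recruitment(rng)

    def _keep(self, mask: np.ndarray) -> None:
        self.dbh = self.dbh[mask]
        self.species = self.species[mask]
        self.patch = self.patch[mask]
        self.last_increment = self.last_increment[mask]
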