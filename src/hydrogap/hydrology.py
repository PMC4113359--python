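"""Daily stand water balance: interception, bucket soil moisture, PET.

The root zone is a single shared bucket of capacity n*z (porosity x depth,
mm) whose normalized moisture s in [0, 1] is the central state variable.
Each day: rainfall is partly intercepted by the canopy (Rutter-type
saturating curve of daily rainfall, saturating at the LAI-dependent canopy
storage), net precipitation infiltrates, trees transpire up to both their
water-use-efficiency demand and the evaporative budget PET - interception,
drainage percolates as a power law of s (saturated hydraulic conductivity
at s = 1), and water above saturation leaves as runoff.  Soil evaporation
and lateral flow are neglected (flat, rain-saturated terrain).

Potential evapotranspiration is Priestley-Taylor, PET = a_PT * D/(D+gamma)
* Rn/L, with net radiation built from daylength-integrated global
radiation (shortwave, albedo-corrected) minus a cloudiness-modulated net
longwave loss.  A water-stress factor omega(s) in [0, 1] (0 at the wilting
point, 1 above the moist-soil threshold theta_msw, linear between)
throttles tree biomass production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilParams", "CanopyHydroParams", "EnergyParams", "SoilState",
    "VanGenuchtenParams", "canopy_storage", "interception",
    "net_precipitation", "drainage", "slope_svp", "daylength_hours",
    "net_radiation", "pet", "transpiration_demand", "cap_transpiration",
    "msw_threshold", "water_stress", "step_soil", "vg_retention",
    "run_water_year",
]


@dataclass(frozen=True)
class SoilParams:
    """Bucket soil parameters.

    Moisture thresholds theta_wp (wilting point) and theta_fc (field
    capacity) are on the normalized-s scale by default; set
    thresholds_volumetric=True to interpret them as volumetric contents
    (divided by porosity internally).  msw_fraction places the moist-soil
    threshold theta_msw between wilting point and field capacity;
    drainage_exponent is the power-law percolation exponent.
    """

    porosity_n: float = 0.757
    depth_z: float = 520.0          # mm
    k_sat: float = 4.0              # mm day-1
    theta_wp: float = 0.125
    theta_fc: float = 0.3
    msw_fraction: float = 1.0
    drainage_exponent: float = 2.0
    thresholds_volumetric: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.porosity_n < 1:
            raise ValueError("porosity_n must be in (0, 1)")
        if self.depth_z <= 0:
            raise ValueError("depth_z must be > 0")
        if self.k_sat < 0:
            raise ValueError("k_sat must be >= 0")
        wp, fc = self.theta_wp, self.theta_fc
        if not (0 <= wp < fc <= 1):
            raise ValueError("need 0 <= theta_wp < theta_fc <= 1")
        if not 0 < self.msw_fraction <= 1:
            raise ValueError("msw_fraction must be in (0, 1]")
        if self.drainage_exponent <= 0:
            raise ValueError("drainage_exponent must be > 0")

    @property
    def capacity_mm(self) -> float:
        """Bucket water capacity n*z (mm)."""
        return self.porosity_n * self.depth_z

    @property
    def wp_s(self) -> float:
        """Wilting point on the normalized-s scale."""
        return (self.theta_wp / self.porosity_n
                if self.thresholds_volumetric else self.theta_wp)

    @property
    def fc_s(self) -> float:
        """Field capacity on the normalized-s scale."""
        return (self.theta_fc / self.porosity_n
                if self.thresholds_volumetric else self.theta_fc)


@dataclass(frozen=True)
class CanopyHydroParams:
    """Canopy interception and water-use parameters.

    The canopy storage curve S(LAI) = S_max*(1 - exp(-f_h*LAI/LAI_max)) is
    anchored by the field calibration S(anchor_lai) = anchor_storage_mm,
    which fixes S_max.  alpha_h is the initial slope of the daily
    interception saturation curve; wue is stand water-use efficiency in
    g CO2 per kg H2O.
    """

    alpha_h: float = 0.7
    f_h: float = 3.0
    lai_max: float = 5.5
    wue: float = 9.0
    anchor_lai: float = 5.0
    anchor_storage_mm: float = 4.9

    def __post_init__(self) -> None:
        if self.alpha_h <= 0 or self.lai_max <= 0 or self.wue <= 0:
            raise ValueError("alpha_h, lai_max and wue must be > 0")
        if self.f_h <= 0 or self.anchor_lai <= 0 or self.anchor_storage_mm <= 0:
            raise ValueError("storage-curve parameters must be > 0")

    @property
    def s_max(self) -> float:
        """Asymptotic canopy storage (mm), fixed by the calibration anchor."""
        return self.anchor_storage_mm / (
            1.0 - math.exp(-self.f_h * self.anchor_lai / self.lai_max))


@dataclass(frozen=True)
class EnergyParams:
    """Radiation/PET constants.

    Global radiation arrives as a daylight-hours mean photon flux in
    umol m-2 s-1; daily shortwave energy converts it with the PAR photon
    energy (J umol-1), the PAR fraction of global shortwave, and the
    astronomical daylength.  Net longwave loss follows the LPJ-style form
    (lw_b + (1-lw_b)*n_i)*(lw_a - T) with sunshine fraction n_i estimated
    from radiation relative to a clear-sky flux.  pt_alpha is the
    Priestley-Taylor coefficient; its default is calibrated so the
    generated current climate yields the regional annual PET (see
    docs/methods.md).
    """

    latitude_deg: float = -41.85
    gamma: float = 65.0             # psychrometric constant, Pa K-1
    latent_heat: float = 2.56e6     # J kg-1
    pt_alpha: float = 1.041         # Priestley-Taylor coefficient (calibrated)
    albedo: float = 0.17
    par_energy_j_per_umol: float = 0.2174
    par_fraction: float = 0.5
    rg_clear_sky: float = 1800.0    # umol m-2 s-1, sunshine-fraction scale
    lw_a: float = 107.0             # W m-2
    lw_b: float = 0.2
    active_days: int = 365          # active photosynthetic period, days


@dataclass
class SoilState:
    """Normalized bucket moisture and derived volumetric content."""

    s: float
    soil: SoilParams

    def __post_init__(self) -> None:
        if not 0 <= self.s <= 1:
            raise ValueError("s must be in [0, 1]")

    @property
    def theta(self) -> float:
        """Volumetric water content theta = s * n."""
        return self.s * self.soil.porosity_n


# ---------------------------------------------------------------------------
# canopy


def canopy_storage(lai_t: float | np.ndarray,
                   params: CanopyHydroParams) -> float | np.ndarray:
    """Canopy water retention capacity S_t (mm) at leaf area index lai_t.

    Saturating in LAI, S(0) = 0, anchored so that the default parameters
    give S(5.0) = 4.9 mm.
    """
    lai = np.asarray(lai_t, dtype=float)
    if np.any(lai < 0):
        raise ValueError("LAI must be >= 0")
    out = params.s_max * (1.0 - np.exp(-params.f_h * lai / params.lai_max))
    return float(out) if out.ndim == 0 else out


def interception(p_d: float | np.ndarray, s_t: float | np.ndarray,
                 alpha_h: float) -> float | np.ndarray:
    """Daily canopy interception Ec_d (mm).

    Rutter-type saturating response Ec = S_t*(1 - exp(-alpha_h*P/S_t)) with
    initial slope alpha_h and asymptote S_t, capped at the day's rainfall.
    """
    p = np.asarray(p_d, dtype=float)
    s = np.asarray(s_t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ec = np.where(s > 0, s * -np.expm1(-alpha_h * p / np.where(s > 0, s, 1.0)),
                      0.0)
    ec = np.minimum(ec, p)
    return float(ec) if ec.ndim == 0 else ec


def net_precipitation(p_d: float, ec_d: float) -> float:
    """Net precipitation Pnet = P - Ec reaching the soil surface (mm)."""
    if ec_d > p_d:
        raise ValueError("interception cannot exceed rainfall")
    return p_d - ec_d


# ---------------------------------------------------------------------------
# soil


def drainage(s: float | np.ndarray, soil: SoilParams) -> float | np.ndarray:
    """Percolation below the root zone, k_sat * s**c, = k_sat at saturation."""
    arr = np.asarray(s, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("s must be in [0, 1]")
    q = soil.k_sat * arr ** soil.drainage_exponent
    return float(q) if q.ndim == 0 else q


def msw_threshold(soil: SoilParams) -> float:
    """Moist-soil threshold theta_msw above which production is unstressed."""
    return soil.wp_s + soil.msw_fraction * (soil.fc_s - soil.wp_s)


def water_stress(s: float | np.ndarray, theta_wp: float,
                 theta_msw: float) -> float | np.ndarray:
    """Water-stress reduction factor omega(s) in [0, 1].

    0 at/below the wilting point, 1 at/above theta_msw, linear between.
    """
    if not theta_wp < theta_msw:
        raise ValueError("need theta_wp < theta_msw")
    arr = np.asarray(s, dtype=float)
    om = np.clip((arr - theta_wp) / (theta_msw - theta_wp), 0.0, 1.0)
    return float(om) if om.ndim == 0 else om


def step_soil(s: float, pnet: float, tr: float, soil: SoilParams,
              q: float | None = None) -> tuple[float, float, float, float]:
    """One explicit daily bucket update.

    Returns (s_new, drainage, runoff, tr_actual).  Drainage is evaluated at
    the start-of-day moisture unless supplied.  Water exceeding saturation
    leaves as runoff; if the tentative store would go negative, transpiration
    (then drainage) is reduced to the available water.  The balance
    pnet = tr + q + runoff + capacity*(s_new - s) closes to round-off.
    """
    if q is None:
        q = drainage(s, soil)
    cap = soil.capacity_mm
    store = s * cap + pnet - tr - q
    if store < 0:
        deficit = -store
        reduce_tr = min(tr, deficit)
        tr -= reduce_tr
        deficit -= reduce_tr
        q = max(0.0, q - deficit)
        store = 0.0
    runoff = max(0.0, store - cap)
    store = min(store, cap)
    return store / cap, q, runoff, tr


# ---------------------------------------------------------------------------
# atmosphere


def slope_svp(t_c: float | np.ndarray) -> float | np.ndarray:
    """Slope of the saturation vapor pressure curve, Delta (Pa K-1).

    Standard Prentice/Haxeltine form
    2.503e6 * exp(17.269*T/(237.3+T)) / (237.3+T)**2.
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -237.0):
        raise ValueError("temperature out of physical range")
    d = 2.503e6 * np.exp(17.269 * t / (237.3 + t)) / (237.3 + t) ** 2
    return float(d) if d.ndim == 0 else d


def daylength_hours(julian_day: int | np.ndarray,
                    latitude_deg: float) -> float | np.ndarray:
    """Astronomical daylength (h) from solar declination and latitude."""
    if abs(latitude_deg) > 90:
        raise ValueError("|latitude| must be <= 90")
    jd = np.asarray(julian_day, dtype=float)
    decl = -0.4093 * np.cos(2.0 * math.pi * (jd + 10.0) / 365.0)
    lat = math.radians(latitude_deg)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    dl = np.arccos(cos_h) / math.pi * 24.0
    return float(dl) if dl.ndim == 0 else dl


def net_radiation(rg_d: float | np.ndarray, t_d: float | np.ndarray,
                  julian_day: int | np.ndarray,
                  energy: EnergyParams) -> float | np.ndarray:
    """Daily net radiation Rn_d (J m-2 day-1), floored at 0 for PET.

    Shortwave: the daylight-mean photon flux Rg_d (umol m-2 s-1) is
    converted to global shortwave energy over the astronomical daylength
    and reduced by the albedo.  Longwave: LPJ-style net loss
    (b + (1-b)*n_i)*(A - T) W m-2 over the full day, with sunshine fraction
    n_i = clip(Rg_d / Rg_clear, 0, 1).
    """
    rg = np.asarray(rg_d, dtype=float)
    if np.any(rg < 0):
        raise ValueError("radiation must be >= 0")
    dl_s = np.asarray(daylength_hours(julian_day, energy.latitude_deg)) * 3600.0
    sw = rg * energy.par_energy_j_per_umol / energy.par_fraction * dl_s
    n_i = np.clip(rg / energy.rg_clear_sky, 0.0, 1.0)
    # PET is a daylight process: both flux terms integrate over daylength
    # (nighttime net radiation is negative and the PET floor is 0 anyway)
    lw = (energy.lw_b + (1.0 - energy.lw_b) * n_i) \
        * (energy.lw_a - np.asarray(t_d, dtype=float)) * dl_s
    rn = np.maximum(0.0, (1.0 - energy.albedo) * sw - lw)
    return float(rn) if rn.ndim == 0 else rn


def pet(rn_d: float | np.ndarray, t_d: float | np.ndarray,
        energy: EnergyParams) -> float | np.ndarray:
    """Priestley-Taylor potential evapotranspiration (mm day-1)."""
    rn = np.asarray(rn_d, dtype=float)
    if np.any(rn < 0):
        raise ValueError("net radiation must be >= 0")
    delta = slope_svp(t_d)
    out = energy.pt_alpha * delta / (delta + energy.gamma) \
        * rn / energy.latent_heat
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# transpiration


def transpiration_demand(pb: float, wue: float, active_days: int) -> float:
    """Daily transpiration demand (mm day-1) from gross production.

    Annual transpiration = PB / WUE with g CO2 m-2 / (g CO2 kg-1 H2O)
    = kg H2O m-2 = mm, spread uniformly over the active photosynthetic
    period.
    """
    if pb < 0:
        raise ValueError("gross production must be >= 0")
    if active_days < 1:
        raise ValueError("active_days must be >= 1")
    return pb / wue / active_days


def cap_transpiration(tr_demand: float, pet_d: float, ec_d: float) -> float:
    """Realized transpiration: demand capped at the budget PET - Ec (>= 0)."""
    return min(tr_demand, max(0.0, pet_d - ec_d))


# ---------------------------------------------------------------------------
# retention curve (verification utility)


@dataclass(frozen=True)
class VanGenuchtenParams:
    """van Genuchten retention-curve parameters (theta_r < theta_s, n > 1)."""

    theta_r: float
    theta_s: float
    alpha_per_kpa: float
    n: float

    def __post_init__(self) -> None:
        if not self.theta_r < self.theta_s:
            raise ValueError("need theta_r < theta_s")
        if self.alpha_per_kpa <= 0:
            raise ValueError("alpha must be > 0")
        if self.n <= 1:
            raise ValueError("shape n must be > 1")


def vg_retention(matric_potential_kpa: float | np.ndarray,
                 vg: VanGenuchtenParams) -> float | np.ndarray:
    """Volumetric water content from matric potential (van Genuchten).

    theta(psi) = theta_r + (theta_s - theta_r)/[1 + (alpha*|psi|)^n]^(1-1/n);
    monotone non-increasing in |psi|, theta_s at saturation, theta_r in the
    dry limit.
    """
    psi = np.abs(np.asarray(matric_potential_kpa, dtype=float))
    m = 1.0 - 1.0 / vg.n
    th = vg.theta_r + (vg.theta_s - vg.theta_r) \
        / (1.0 + (vg.alpha_per_kpa * psi) ** vg.n) ** m
    return float(th) if th.ndim == 0 else th


# ---------------------------------------------------------------------------
# daily loop


def run_water_year(rain: np.ndarray, temp: np.ndarray, rg: np.ndarray,
                   julian_day: np.ndarray, lai: float,
                   demand_per_day: float | np.ndarray, s0: float,
                   soil: SoilParams, canopy: CanopyHydroParams,
                   energy: EnergyParams,
                   cap_interception_by_pet: bool = True,
                   pet_d: np.ndarray | None = None,
                   ) -> dict[str, np.ndarray]:
    """Run the daily water balance over one weather block (usually a year).

    Order per day: PET -> transpiration (demand, stress, PET cap) ->
    interception -> drainage -> storage update -> runoff.  When
    cap_interception_by_pet is set, interception (an evaporative loss) is
    limited to the evaporative budget left after transpiration, so daily
    ET = Tr + Ec never exceeds PET_d and Tr <= PET_d - Ec_d holds by
    construction; without the cap, interception is limited only by the
    day's rainfall.

    demand_per_day is the transpiration demand posed each day (scalar or
    per-day array, mm day-1); pet_d may be supplied to avoid recomputing
    the radiation balance.

    Returns per-day arrays rain, interception, net_precip, pet,
    transpiration, drainage, runoff, s (end of day), omega, plus the
    transpiration demand actually posed each day under "demand".
    """
    rain = np.asarray(rain, dtype=float)
    n = rain.size
    s_t = canopy_storage(lai, canopy)
    ec_raw = interception(rain, s_t, canopy.alpha_h)
    if pet_d is None:
        pet_d = pet(net_radiation(rg, temp, julian_day, energy), temp, energy)
    demand = np.broadcast_to(np.asarray(demand_per_day, dtype=float),
                             rain.shape)

    wp = soil.wp_s
    msw = msw_threshold(soil)
    k_sat = soil.k_sat
    c = soil.drainage_exponent
    cap = soil.capacity_mm
    cap_by_pet = cap_interception_by_pet

    s = float(s0)
    out_s = np.empty(n)
    out_tr = np.empty(n)
    out_q = np.empty(n)
    out_ro = np.empty(n)
    out_om = np.empty(n)
    out_ec = np.empty(n)
    span = msw - wp
    for i in range(n):
        om = (s - wp) / span
        om = 0.0 if om < 0.0 else (1.0 if om > 1.0 else om)
        # transpiration demand has first call on the evaporative budget;
        # interception evaporates from the remainder (daily ET never
        # exceeds PET, and Tr <= PET - Ec holds by construction)
        tr = demand[i] * om
        if tr > pet_d[i]:
            tr = pet_d[i]
        ec = ec_raw[i]
        if cap_by_pet:
            rest = pet_d[i] - tr
            if ec > rest:
                ec = rest if rest > 0.0 else 0.0
        pnet = rain[i] - ec
        q = k_sat * s ** c
        store = s * cap + pnet - tr - q
        if store < 0.0:
            short = -store
            take = tr if tr < short else short
            tr -= take
            short -= take
            q = q - short if q > short else 0.0
            store = 0.0
        if store > cap:
            ro = store - cap
            store = cap
        else:
            ro = 0.0
        s = store / cap
        out_s[i] = s
        out_tr[i] = tr
        out_q[i] = q
        out_ro[i] = ro
        out_om[i] = om
        out_ec[i] = ec
    return {
        "rain": rain, "interception": out_ec, "net_precip": rain - out_ec,
        "pet": pet_d,
        "transpiration": out_tr, "drainage": out_q, "runoff": out_ro,
        "s": out_s, "omega": out_om,
        "demand": np.array(demand, dtype=float),
    }
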