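"""Seeded case-control cohort generator for instrument validation.

The generator emulates the structure of the clinical validation study: a
cancer group (default n = 186) and an age-matched control group (default
n = 95) whose total-score distributions are calibrated to the reported
group means and standard deviations (32.54 +/- 17.58 vs 8.72 +/- 3.56).

Model
-----
Each subject carries a latent severity ``s`` in [0, 1].  Severity is drawn
per group by (i) sampling a target total score ``T`` from a truncated
normal on [0, 100] whose *truncated* moments are solved to match the
group targets (with the measurement-noise variance of the links
subtracted), and (ii) inverting the expected-score link ``m(s)`` so that
``E[total | s] = T``.  All observable inputs are monotone links of ``s``
plus independent noise:

* percent weight loss: continuous monotone link, band-quantised by the
  scoring rules; LBM depletion switches on in the upper severity range;
* lab markers: marker m turns abnormal when ``s`` (plus noise) crosses a
  per-marker severity cut; the cuts are staggered so the expected marker
  points grow linearly with severity;
* ordinal items: graded-threshold model -- item latent
  ``g = s + tau * eps`` with ``tau`` set by ``item_loading`` (loading 1 =
  noise free), quantised to the item's response levels with fixed
  per-item phase offsets (dithering, so aggregate scores vary smoothly);
* ECOG and clinician rating: Gaussian-copula discretisations with latent
  correlation ``criterion_rho`` to severity (patients; controls are
  scored 0 as in the study population).

Missingness is MCAR over lab and item cells at ``missing_rate``.
Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instrument import InstrumentDefinition, load_instrument

_LBM_CUT = 0.75           # severity above which LBM depletion switches on
_GH_POINTS = 41           # Gauss-Hermite nodes for link expectations
_F_GRID = 241             # severity grid for inverting the expected score

# Severity order in which markers turn abnormal (clinically: inflammation
# and hypoalbuminemia early, overt metabolic failure late).
_MARKER_ORDER = (
    "crp", "albumin", "hemoglobin", "il6", "prealbumin", "lactate",
    "lymphocytes", "triglycerides", "urea", "ros", "homa",
)

# Cosmetic tumor-site frequencies from the study's diagnosis table.
_TUMOR_SITES = (
    ("lung", 32), ("breast", 27), ("head_and_neck", 21), ("colon", 17),
    ("ovary", 13), ("pancreas", 11), ("prostate", 10),
    ("upper_gastrointestinal", 10), ("rectum", 8), ("bile_glands", 7),
    ("endometrium", 4), ("liver", 3), ("kidney", 3), ("other", 17),
)

_ECOG_PROBS = (0.14, 0.24, 0.34, 0.24, 0.04)   # patients; 0-1 ~38%, controls all 0
_CLINICIAN_PROBS = (0.10, 0.12, 0.12, 0.11, 0.10, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05)


class SimulationError(ValueError):
    pass


@dataclass
class CohortParams:
    """Generator parameters; defaults reproduce the study conditions."""

    n_cancer: int = 186
    n_control: int = 95
    cancer_mean: float = 32.54
    cancer_sd: float = 17.58
    control_mean: float = 8.72
    control_sd: float = 3.56
    item_loading: float = 0.8      # factor loading of items on their component
    marker_noise: float = 0.05     # sd of severity noise in lab/weight links
    criterion_rho: float = 0.4     # latent severity-criterion correlation
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer <= 0 or self.n_control <= 0:
            raise SimulationError("group sizes must be positive")
        if not (0 <= self.cancer_mean <= 100 and 0 <= self.control_mean <= 100):
            raise SimulationError("infeasible target means (must lie in [0, 100])")
        if self.cancer_sd <= 0 or self.control_sd <= 0:
            raise SimulationError("target SDs must be positive")
        if not 0 <= self.missing_rate <= 1:
            raise SimulationError("missing_rate must be in [0, 1]")
        if not 0 < self.item_loading <= 1:
            raise SimulationError("item_loading must be in (0, 1]")
        if not 0 <= self.criterion_rho <= 1:
            raise SimulationError("criterion_rho must be in [0, 1]")


# ---------------------------------------------------------------------------
# Link functions (shared by realized draws and their expectations)
# ---------------------------------------------------------------------------

def _marker_cuts(instrument: InstrumentDefinition) -> dict[str, float]:
    """Severity cut per marker: staggered so E[points] tracks budget * s."""
    rules = {r.marker_id: r for r in instrument.marker_rules()}
    budget = instrument.component("IMD").budget
    cuts: dict[str, float] = {}
    cum = 0.0
    for mid in _MARKER_ORDER:
        if mid not in rules:
            continue
        pts = rules[mid].points
        cuts[mid] = (cum + pts / 2.0) / budget
        cum += pts
    return cuts


def _weight_loss_pct(f: np.ndarray) -> np.ndarray:
    """Continuous monotone severity -> percent weight loss link.

    Half-band offset centres the band quantisation, keeping the expected
    band points close to the 40 * s target.
    """
    f = np.clip(f, 0.0, 1.0)
    t = np.clip(40.0 * f - 10.0 * (f > _LBM_CUT), 0.0, 30.0)
    return np.clip((t / 30.0) * 20.0 - 2.5, 0.0, None)


def _band_points(wl: np.ndarray, instrument: InstrumentDefinition) -> np.ndarray:
    bands = instrument.component("BWC").bands
    pts = np.full(np.shape(wl), np.nan)
    remaining = np.ones(np.shape(wl), dtype=bool)
    for band in bands:
        hit = remaining & (wl <= band.upper)
        pts[hit] = band.points
        remaining &= ~hit
    return pts


def _item_phases(n_items: int) -> np.ndarray:
    """Fixed per-item dither offsets (golden-ratio sequence)."""
    golden = (math.sqrt(5.0) - 1.0) / 2.0
    return np.mod(0.5 + golden * np.arange(n_items), 1.0)


def _item_fraction(g: np.ndarray, n_levels: int, phase: float) -> np.ndarray:
    """Quantised severity fraction of an item given its latent ``g``."""
    q = np.floor(np.clip(g, 0.0, 1.0) * (n_levels - 1) + phase)
    return np.clip(q, 0, n_levels - 1) / (n_levels - 1)


def _item_tau(params: CohortParams) -> float:
    """Item noise sd implied by the loading and the pooled severity spread."""
    lam = params.item_loading
    p = params.n_cancer / (params.n_cancer + params.n_control)
    pooled_var = (
        p * params.cancer_sd ** 2
        + (1 - p) * params.control_sd ** 2
        + p * (1 - p) * (params.cancer_mean - params.control_mean) ** 2
    )
    sd_f = math.sqrt(pooled_var) / 100.0
    return sd_f * math.sqrt(1.0 - lam * lam) / lam


def _gh() -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(_GH_POINTS)
    return nodes * math.sqrt(2.0), weights / math.sqrt(math.pi)


def _expected_score_curve(
    instrument: InstrumentDefinition, params: CohortParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid of f, E[total | f] and Var[total | f] under the links."""
    f = np.linspace(0.0, 1.0, _F_GRID)
    z, w = _gh()
    nu = max(params.marker_noise, 1e-9)
    tau = max(_item_tau(params), 1e-9)
    bwc = instrument.component("BWC")

    mean = np.zeros_like(f)
    var = np.zeros_like(f)

    # weight-loss band (noise on the severity scale)
    ft = f[:, None] + nu * z[None, :]
    band = _band_points(_weight_loss_pct(ft), instrument)
    e1, e2 = band @ w, (band ** 2) @ w
    mean += e1
    var += e2 - e1 ** 2

    # LBM depletion: bernoulli in the noisy severity
    p_lbm = stats.norm.sf(_LBM_CUT, loc=f, scale=nu)
    mean += bwc.lbm_points * p_lbm
    var += bwc.lbm_points ** 2 * p_lbm * (1 - p_lbm)

    # markers: independent bernoullis
    for mid, cut in _marker_cuts(instrument).items():
        rule = next(r for r in instrument.marker_rules() if r.marker_id == mid)
        p_ab = stats.norm.sf(cut, loc=f, scale=nu)
        mean += rule.points * p_ab
        var += rule.points ** 2 * p_ab * (1 - p_ab)

    # ordinal items: graded thresholds with per-item phases
    for comp_name in ("PHP", "ANO", "QoL"):
        comp = instrument.component(comp_name)
        phases = _item_phases(len(comp.items))
        per_item = comp.item_max_points()
        for item, phase in zip(comp.items, phases):
            g = f[:, None] + tau * z[None, :]
            pts = per_item * _item_fraction(g, item.n_levels, phase)
            e1, e2 = pts @ w, (pts ** 2) @ w
            mean += e1
            var += e2 - e1 ** 2

    return f, mean, var


def _solve_truncnorm(mean: float, sd: float) -> tuple[float, float]:
    """Parameters of a [0, 100]-truncated normal with given truncated moments."""

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    return mu, sigma


def _draw_targets(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    mu, sigma = _solve_truncnorm(mean, sd)
    a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _discretize(latent: np.ndarray, probs) -> np.ndarray:
    """Map standard-normal latents to ordinal levels with given marginals."""
    cum = np.cumsum(probs)[:-1]
    thresholds = stats.norm.ppf(cum)
    return np.searchsorted(thresholds, latent).astype(int)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(
    params: CohortParams | None = None,
    seed: int | None = None,
    instrument: InstrumentDefinition | None = None,
) -> pd.DataFrame:
    """Generate one case-control cohort table.

    Returns a DataFrame with one row per subject: identifiers and group,
    cosmetic demographics, the weight pair, LBM depletion flag, the eleven
    lab markers, every questionnaire item of the full instrument, the two
    external criteria, and the true latent ``severity`` column (ignored by
    scoring; kept for recovery tests).
    """
    params = params or CohortParams()
    params.validate()
    if seed is not None:
        params = CohortParams(**{**asdict(params), "seed": seed})
    instrument = instrument or load_instrument("casco")
    rng = np.random.default_rng(params.seed)

    # --- severity via calibrated score targets --------------------------
    f_grid, m_grid, v_grid = _expected_score_curve(instrument, params)
    # make the inversion grid strictly increasing across flat stretches
    m_mono = np.maximum.accumulate(m_grid) + 1e-9 * np.arange(len(m_grid))

    groups, targets = [], []
    for group, n, mean, sd in (
        ("cancer", params.n_cancer, params.cancer_mean, params.cancer_sd),
        ("control", params.n_control, params.control_mean, params.control_sd),
    ):
        # average link-noise variance under this group's severity range,
        # subtracted from the target so realized spread stays on target
        t0 = _draw_targets(rng, n, mean, sd)
        f0 = np.interp(t0, m_mono, f_grid)
        v_bar = float(np.interp(f0, f_grid, v_grid).mean())
        sd_adj = math.sqrt(max(sd * sd - v_bar, (0.3 * sd) ** 2))
        t = _draw_targets(rng, n, mean, sd_adj)
        groups.append(group)
        targets.append(t)

    t_all = np.concatenate(targets)
    group_col = np.repeat(
        ["cancer", "control"], [params.n_cancer, params.n_control]
    )
    n_total = len(t_all)
    severity = np.interp(t_all, m_mono, f_grid)

    nu = max(params.marker_noise, 0.0)
    tau = _item_tau(params)

    # --- demographics (cosmetic) ----------------------------------------
    is_cancer = group_col == "cancer"
    sex = np.where(
        rng.random(n_total) < np.where(is_cancer, 0.59, 0.55), "male", "female"
    )
    age = np.clip(
        rng.normal(np.where(is_cancer, 65.27, 56.34), np.where(is_cancer, 11.96, 6.60)),
        18, 95,
    ).round(1)
    site_names = [s for s, _ in _TUMOR_SITES]
    site_p = np.array([c for _, c in _TUMOR_SITES], dtype=float)
    site_p /= site_p.sum()
    tumor_site = np.where(
        is_cancer, rng.choice(site_names, size=n_total, p=site_p), "none"
    )

    # --- body weight ------------------------------------------------------
    wl = _weight_loss_pct(severity + nu * rng.standard_normal(n_total))
    weight_pre = np.clip(
        rng.normal(np.where(is_cancer, 74.0, 76.73), np.where(is_cancer, 26.2, 15.2)),
        42, 140,
    ).round(1)
    # gram resolution keeps the recovered loss faithful to the link
    weight_cur = (weight_pre * (1.0 - wl / 100.0)).round(3)
    lbm = (severity + nu * rng.standard_normal(n_total)) > _LBM_CUT

    # --- lab markers ------------------------------------------------------
    labs: dict[str, np.ndarray] = {}
    cuts = _marker_cuts(instrument)
    rules = {r.marker_id: r for r in instrument.marker_rules()}
    for mid in _MARKER_ORDER:
        rule = rules[mid]
        abnormal = (severity + nu * rng.standard_normal(n_total)) > cuts[mid]
        cut_val = np.array(
            [rule.cut_for(sx) for sx in sex]
        )
        spread = 0.3 * np.maximum(np.abs(cut_val), 1.0)
        offset = spread * (0.1 + 0.6 * np.abs(rng.standard_normal(n_total))
                           + 0.5 * severity)
        sign = 1.0 if rule.abnormal_direction == "high" else -1.0
        value = np.where(abnormal, cut_val + sign * offset, cut_val - sign * offset)
        labs[mid] = np.maximum(value, 0.01 * np.abs(cut_val)).round(3)

    # --- questionnaire items ---------------------------------------------
    responses: dict[str, np.ndarray] = {}
    for comp_name in ("PHP", "ANO", "QoL"):
        comp = instrument.component(comp_name)
        phases = _item_phases(len(comp.items))
        for item, phase in zip(comp.items, phases):
            g = severity + tau * rng.standard_normal(n_total)
            frac = _item_fraction(g, item.n_levels, float(phase))
            q = np.rint(frac * (item.n_levels - 1)).astype(int)
            level = (item.n_levels - q) if item.reverse_coded else (1 + q)
            responses[item.item_id] = level

    # --- external criteria ------------------------------------------------
    rho = params.criterion_rho
    ecog = np.zeros(n_total, dtype=int)
    clin = np.zeros(n_total, dtype=int)
    pat = np.where(is_cancer)[0]
    if len(pat) >= 2:
        z = (severity[pat] - severity[pat].mean()) / max(severity[pat].std(), 1e-9)
        for out, probs in ((ecog, _ECOG_PROBS), (clin, _CLINICIAN_PROBS)):
            latent = rho * z + math.sqrt(max(1 - rho * rho, 0.0)) * \
                rng.standard_normal(len(pat))
            out[pat] = _discretize(latent, probs)
    ctrl = np.where(~is_cancer)[0]
    clin[ctrl] = (rng.random(len(ctrl)) < 0.2).astype(int)  # 0 or 1

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n_total)],
            "group": group_col,
            "sex": sex,
            "age": age,
            "tumor_site": tumor_site,
            "weight_preillness": weight_pre,
            "weight_current": weight_cur,
            "lbm_depleted": lbm.astype(float),
            **{mid: labs[mid] for mid in _MARKER_ORDER},
            **responses,
            "ecog": ecog,
            "clinician_rating": clin,
            "severity": severity.round(6),
        }
    )
    if params.missing_rate > 0:
        df = inject_missing(
            df, params.missing_rate, seed=int(rng.integers(0, 2 ** 31))
        )
    df.attrs["params"] = asdict(params)
    return df


def inject_missing(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """MCAR masking of lab and questionnaire cells at the given rate.

    Identifiers, group labels, demographics and external criteria are
    never masked.
    """
    if not 0 <= rate <= 1:
        raise SimulationError("rate must be in [0, 1]")
    out = cohort.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    maskable = [
        c for c in out.columns
        if c in _MARKER_ORDER or c[:3] in ("php", "ano", "qol")
    ]
    for col in maskable:
        mask = rng.random(len(out)) < rate
        out[col] = out[col].astype(float).where(~mask, np.nan)
    return out


def maskable_columns(cohort: pd.DataFrame) -> list[str]:
    return [
        c for c in cohort.columns
        if c in _MARKER_ORDER or c[:3] in ("php", "ano", "qol")
    ]
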