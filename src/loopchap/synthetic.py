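"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's data-generating processes so each stage
is testable without any download:

* a mutant panel of loop motif sets whose true chaperone activity is linear
  in combined hydropathy (plus Gaussian panel noise, clamped to [0, 100]);
* turbidity plates whose control is a saturating logistic and whose variant
  traces have expected AUC ratio equal to activity/100;
* ThT dilution-series plates produced from the integrated rate law with
  exactly one rate constant suppressed per chaperone:substrate ratio;
* SEC chromatograms as Gaussian peaks on a log-linear calibration with
  subunit-count truth built in.

No generator hardcodes the study's (figure-only) wild-type sequences: the
panel archetypes are synthetic stand-ins that mirror the mutational design
(EGR swaps, SS/SAS polar substitutions, anchor T→W).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import LoopchapError
from .hydropathy import HydropathyScale, MotifSet, motif_hydropathy
from .kinetics import KineticParams, simulate_mass_fraction
from .qc import SECCalibration, SECChromatogram

_HYDROPHOBIC = "ILVFM"
_ALL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Synthetic stand-in for the wild-type loop motifs (hydrophobic tripeptides
#: plus the T206 anchor, mirroring the real panel's architecture).
_WT_ARCHETYPE = ("FIL", "VLI", "ILF", "T")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with the study's conditions as defaults."""

    seed: int
    n_variants: int = 12
    true_slope: float = -3.1       # mass % per biological-scale unit
    true_intercept: float = 42.0   # mass % at combined hydropathy 0
    noise_sd_pct: float = 3.0      # panel-level activity noise (sd, %)
    turbidity_noise_au: float = 0.005  # additive instrument noise (A360)
    n_turbidity_replicates: int = 3
    tht_noise_frac: float = 0.02   # multiplicative ThT noise
    n_tht_replicates: int = 4
    kinetics: KineticParams = field(
        default_factory=lambda: KineticParams(k_n=4.6e-5, k_plus=3e6, k_2=6.2e3)
    )
    suppression_target: str = "k_2"
    suppression_factors: tuple = ((0.0, 1.0), (10.0, 0.5), (50.0, 0.2), (100.0, 0.1))
    tht_t_max: float = 1.2e5       # s
    tht_dt: float = 600.0          # s
    sec_monomer_mw: float = 13300.0
    sec_subunits_peak: int = 25
    sec_subunits_range: tuple[int, int] = (18, 30)

    def __post_init__(self):
        if self.seed is None:
            raise LoopchapError("GeneratorConfig requires an explicit seed")
        for name in ("noise_sd_pct", "turbidity_noise_au", "tht_noise_frac"):
            if getattr(self, name) < 0:
                raise LoopchapError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def _clamp(a):
    return np.clip(a, 0.0, 100.0)


def gen_variant_panel(
    cfg: GeneratorConfig, scale: HydropathyScale
) -> tuple[list[MotifSet], pd.DataFrame]:
    """Mutant panel spanning a wide hydropathy range, with activity truth.

    The first entries are fixed archetypes (wt-like, EGR swaps of one to
    three motifs, SS/SAS polar substitutions, T→W anchor swap, ΔL); any
    remaining slots are random tripeptides.  True activity is
    ``clamp(intercept + slope · combined + noise, 0, 100)``.
    """
    if cfg.n_variants < 3:
        raise LoopchapError("panel needs at least 3 variants")
    m1, m2, m3, anchor = _WT_ARCHETYPE
    archetypes = [
        MotifSet("wt", m1, m2, m3, anchor),
        MotifSet("m1_EGR", "EGR", m2, m3, anchor),
        MotifSet("m2_EGR", m1, "EGR", m3, anchor),
        MotifSet("m3_EGR", m1, m2, "EGR", anchor),
        MotifSet("all_EGR", "EGR", "EGR", "EGR", anchor),
        MotifSet("m1_SS", "SSL", m2, m3, anchor),
        MotifSet("m2_SAS", m1, "SAS", m3, anchor),
        MotifSet("m3_SAS", m1, m2, "SAS", anchor),
        MotifSet("T206W", m1, m2, m3, "W"),
        MotifSet("delta_loop", "", "", "", ""),
    ]
    rng = cfg.rng(1)
    panel = archetypes[: cfg.n_variants]
    # random variants are rejection-sampled onto the hydropathy interval
    # where the linear map stays inside [0, 100], so the zero-noise truth
    # is exactly linear (the clamp only ever acts on the noise term)
    if cfg.true_slope < 0:
        x_lo = (100.0 - cfg.true_intercept) / cfg.true_slope
        x_hi = -cfg.true_intercept / cfg.true_slope
    elif cfg.true_slope > 0:
        x_lo = -cfg.true_intercept / cfg.true_slope
        x_hi = (100.0 - cfg.true_intercept) / cfg.true_slope
    else:
        x_lo, x_hi = -np.inf, np.inf
    i = 0
    while len(panel) < cfg.n_variants:
        tri = ["".join(rng.choice(list(_ALL_RESIDUES), 3)) for _ in range(3)]
        cand = MotifSet(f"rand{i:02d}", *tri, anchor)
        if x_lo <= motif_hydropathy(cand, scale).combined <= x_hi:
            panel.append(cand)
            i += 1
    scores = np.array([motif_hydropathy(m, scale).combined for m in panel])
    noise = rng.normal(0.0, cfg.noise_sd_pct, size=len(panel)) \
        if cfg.noise_sd_pct > 0 else np.zeros(len(panel))
    activity = _clamp(cfg.true_intercept + cfg.true_slope * scores + noise)
    truth = pd.DataFrame(
        {
            "variant_id": [m.variant_id for m in panel],
            "combined": scores,
            "true_activity_pct": activity,
        }
    )
    return panel, truth


def _logistic_control(times, amax=0.5, t_half=1800.0, rate=1.0 / 300.0):
    return amax / (1.0 + np.exp(np.clip(rate * (t_half - times), -700, 700)))


def gen_turbidity_panel(
    cfg: GeneratorConfig, activities: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turbidity plate (long CSV form) + well map for a variant panel.

    ``activities`` needs columns variant_id / true_activity_pct in [0, 100].
    The substrate-alone control is a saturating logistic in A360 sampled on
    the 90 s plate cadence; each variant's traces are the control scaled by
    activity/100 (so the expected AUC ratio is the activity) plus additive
    Gaussian instrument noise.
    """
    if not activities["true_activity_pct"].between(0, 100).all():
        raise LoopchapError("activities must lie in [0, 100]")
    rng = cfg.rng(2)
    times = np.arange(0.0, 3600.0 + 1, 90.0)
    control = _logistic_control(times)
    rows, map_rows = [], []
    well_idx = 0

    def add_well(name, chaperone, ratio, replicate, scale_factor):
        nonlocal well_idx
        well = f"W{well_idx:03d}"
        well_idx += 1
        noise = rng.normal(0.0, cfg.turbidity_noise_au, size=times.size) \
            if cfg.turbidity_noise_au > 0 else 0.0
        signal = control * scale_factor + noise
        for t, s in zip(times, signal):
            rows.append({"time_s": t, "well": well, "signal": s})
        map_rows.append(
            {"well": well, "substrate": "CS", "chaperone": chaperone,
             "ratio": ratio, "replicate": replicate}
        )

    for rep in range(cfg.n_turbidity_replicates):
        add_well("ctrl", "", np.nan, rep, 1.0)
    for row in activities.itertuples():
        for rep in range(cfg.n_turbidity_replicates):
            add_well(row.variant_id, row.variant_id, 1.0, rep,
                     row.true_activity_pct / 100.0)
    return pd.DataFrame(rows), pd.DataFrame(map_rows)


def suppressed_params(cfg: GeneratorConfig, factor: float) -> KineticParams:
    """Baseline kinetics with the configured target constant scaled by ``factor``."""
    p = cfg.kinetics
    key = {"k_n": "k_n", "k_plus": "k_plus", "k_2": "k_2"}[cfg.suppression_target]
    return replace(p, **{key: getattr(p, key) * factor})


def gen_tht_panel(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """ThT plate + well map + ground truth for a chaperone dilution series.

    One rate constant (``cfg.suppression_target``) is suppressed by the
    configured factor at each chaperone:Aβ42 ratio; curves come from the
    integrated rate law, scaled to fluorescence (F0 + A·M) with
    multiplicative Gaussian noise on the fibril signal, 4 replicates.
    """
    rng = cfg.rng(3)
    times = np.arange(0.0, cfg.tht_t_max + 1, cfg.tht_dt)
    f0, amp = 100.0, 1000.0
    rows, map_rows = [], []
    truth = {"suppression_target": cfg.suppression_target, "factors": {},
             "f0": f0, "amplitude": amp, "kinetics": cfg.kinetics}
    well_idx = 0
    for ratio, factor in cfg.suppression_factors:
        p = suppressed_params(cfg, factor)
        m = simulate_mass_fraction(p, times)
        truth["factors"][float(ratio)] = float(factor)
        for rep in range(cfg.n_tht_replicates):
            well = f"T{well_idx:03d}"
            well_idx += 1
            eps = rng.normal(0.0, cfg.tht_noise_frac, size=times.size) \
                if cfg.tht_noise_frac > 0 else 0.0
            signal = f0 + amp * m * (1.0 + eps)
            for t, s in zip(times, signal):
                rows.append({"time_s": t, "well": well, "signal": s})
            map_rows.append(
                {"well": well, "substrate": "Ab42", "chaperone": "BRICHOS",
                 "ratio": float(ratio), "replicate": rep}
            )
    return pd.DataFrame(rows), pd.DataFrame(map_rows), truth


def gen_sec(cfg: GeneratorConfig) -> tuple[SECChromatogram, SECCalibration, dict]:
    """Gaussian SEC peak on a log-linear calibration with subunit truth.

    The peak center maps to exactly ``sec_subunits_peak`` × monomer MW and
    the half-height crossings to the ends of ``sec_subunits_range`` (the
    two flanks have different widths, so the peak is piecewise Gaussian).
    """
    cal = SECCalibration.from_standards(
        [(9.0, 5.6e5), (11.0, 1.8e5), (13.0, 5.6e4), (15.0, 1.8e4)]
    )
    mw = cfg.sec_monomer_mw
    lo_n, hi_n = cfg.sec_subunits_range
    if not lo_n <= cfg.sec_subunits_peak <= hi_n:
        raise LoopchapError("sec_subunits_range must bracket sec_subunits_peak")
    v_center = cal.volume_of(cfg.sec_subunits_peak * mw)
    v_left = cal.volume_of(hi_n * mw)    # larger species elute earlier
    v_right = cal.volume_of(lo_n * mw)
    hwhm_to_sigma = 1.0 / np.sqrt(2.0 * np.log(2.0))
    sig_l = (v_center - v_left) * hwhm_to_sigma
    sig_r = (v_right - v_center) * hwhm_to_sigma
    volumes = np.arange(6.0, 18.0, 0.01)
    sigma = np.where(volumes < v_center, sig_l, sig_r)
    a280 = np.exp(-0.5 * ((volumes - v_center) / sigma) ** 2)
    chrom = SECChromatogram(elution_volume=volumes, a280=a280,
                            column_id="synthetic")
    truth = {
        "subunits_peak": cfg.sec_subunits_peak,
        "subunits_range": cfg.sec_subunits_range,
        "monomer_mw": mw,
        "peak_volume": float(v_center),
    }
    return chrom, cal, truth
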