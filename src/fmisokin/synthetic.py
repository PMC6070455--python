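"""Synthetic FMISO PET / perfusion-CT study generator.

Produces complete, self-consistent studies with the statistical structure
the analysis pipeline assumes: a bolus-plus-washout arterial input function
sampled onto the blood frame schedule, tumor TACs generated by a chosen
compartment model on the tumor schedule (45-min dynamic block plus 10-min
frames at 2 h and 4 h), frame-wise Gaussian noise with variance proportional
to the inverse of the fit weights, and perfusion-CT curves whose blood flow
is linked to the PET delivery constant through K1 = BF * E with
E = 1 - exp(-PS/BF).  Everything is reproducible from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import models as M
from .aath import AATHParameters, AttenuationCurve, aath_tac
from .simulation import NoiseModel
from .tac import (
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
    s1_schedule,
    s2_schedule,
    write_tac,
)

__all__ = [
    "CohortConfig",
    "StudyBundle",
    "feng_curve",
    "generate_input_function",
    "generate_cohort",
    "gamma_variate",
    "DEFAULT_TRUTH_RANGES",
]


# ---------------------------------------------------------------------------
# Arterial input function (stands in for the descending-aorta IDIF)
# ---------------------------------------------------------------------------

#: Default bolus-plus-washout shape: a fast bolus term A1*t*exp(-l1*t) plus
#: two washout exponentials.  Amplitudes kBq/mL, rates min^-1; the slow
#: component's half-life (~230 min) reflects slow FMISO blood clearance.
FENG_DEFAULTS = {"a1": 300.0, "l1": 4.0, "a2": 8.0, "l2": 0.25, "a3": 12.0, "l3": 0.003}


def feng_curve(t_min, a1=None, l1=None, a2=None, l2=None, a3=None, l3=None, amplitude=1.0):
    """Feng-style input curve: zero before injection, bolus peak within 60 s.

    C(t) = A1 t e^{-l1 t} + A2 (e^{-l2 t} - e^{-l1 t}) + A3 (e^{-l3 t} - e^{-l1 t})

    Non-negative for l1 >= l2, l3; C(0) = 0.
    """
    d = FENG_DEFAULTS
    a1 = d["a1"] if a1 is None else a1
    l1 = d["l1"] if l1 is None else l1
    a2 = d["a2"] if a2 is None else a2
    l2 = d["l2"] if l2 is None else l2
    a3 = d["a3"] if a3 is None else a3
    l3 = d["l3"] if l3 is None else l3
    t = np.asarray(t_min, float)
    e1 = np.exp(-l1 * np.maximum(t, 0.0))
    c = a1 * np.maximum(t, 0.0) * e1
    c = c + a2 * (np.exp(-l2 * np.maximum(t, 0.0)) - e1)
    c = c + a3 * (np.exp(-l3 * np.maximum(t, 0.0)) - e1)
    return amplitude * np.where(t <= 0, 0.0, c)


def generate_input_function(
    schedule: FrameSchedule | None = None, amplitude: float = 1.0, **feng_params
) -> InputFunction:
    """Blood input function: the Feng curve frame-averaged onto ``schedule``.

    Defaults to the S2 blood schedule with the 2 h / 4 h late frames.  Frame
    averaging uses a fine sub-sampling of each frame so the stored TAC is
    what an image-derived blood region would measure.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    sched = s2_schedule() if schedule is None else schedule
    vals = np.empty(sched.n_frames)
    for i in range(sched.n_frames):
        ts = np.linspace(sched.start_s[i], sched.end_s[i], 21) / 60.0
        vals[i] = feng_curve(ts, amplitude=amplitude, **feng_params).mean()
    tac = TimeActivityCurve(sched, vals, label="blood")
    return InputFunction(tac)


def gamma_variate(t_s, amp=350.0, t0_s=8.0, alpha=3.0, beta_s=2.5):
    """Gamma-variate first-pass bolus in HU: amp * (x/ab)^a * e^{a - x/b}."""
    t = np.asarray(t_s, float)
    x = np.maximum(t - t0_s, 0.0)
    with np.errstate(invalid="ignore"):
        y = amp * (x / (alpha * beta_s)) ** alpha * np.exp(alpha - x / beta_s)
    return np.where(x <= 0, 0.0, y)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Truth sampling ranges for the default three-tissue irreversible model;
#: generator defaults chosen so a subset of tumors shows a 4-h TBR above 1.4.
DEFAULT_TRUTH_RANGES = {
    "vB": (0.02, 0.2),
    "K1": (0.1, 0.6),
    "k2": (0.1, 0.6),
    "k3": (0.005, 0.1),
    "k4": (0.005, 0.1),
    "k5": (0.005, 0.05),
    # extensions for the reversible three-tissue and the four-tissue chains
    "k6": (0.005, 0.05),
    "k7": (0.005, 0.05),
    "k8": (0.005, 0.05),
}


@dataclasses.dataclass
class CohortConfig:
    """Configuration of one synthetic study; the master seed is mandatory."""

    seed: int
    n_tumors: int = 15
    n_scans_per_voi: int = 2
    truth_model: str = "3C5K"
    truth_ranges: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_TRUTH_RANGES))
    noise_scale_mean: float = 0.6
    noise_scale_sd: float = 0.3
    noise_scale_min: float = 0.1
    pct_noise_sd_hu: float = 5.0
    ps_bf_ratio_range: tuple = (5.0, 10.0)
    vp_range: tuple = (0.03, 0.12)
    ve_range: tuple = (0.2, 0.5)
    pct_delay_range_s: tuple = (2.0, 6.0)

    def validate(self):
        if self.n_tumors < 1 or self.n_scans_per_voi < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.noise_scale_mean < 0 or self.noise_scale_sd < 0:
            raise ValueError("noise scale moments must be >= 0")
        spec = M.model_spec(self.truth_model)
        for name in spec.free_param_names:
            base = name.split("-")[0]
            if base not in self.truth_ranges:
                raise ValueError(f"no truth range for parameter {base}")
            lo, hi = self.truth_ranges[base]
            if not 0 <= lo <= hi:
                raise ValueError(f"bad range for {base}: ({lo}, {hi})")
        if self.ps_bf_ratio_range[0] <= 0:
            raise ValueError("PS/BF ratio must be positive")


@dataclasses.dataclass
class StudyBundle:
    """Everything one synthetic study contains, in memory."""

    config: CohortConfig
    input_fn: InputFunction
    truths: list  # KineticParameters per VOI
    clean_tacs: list  # TimeActivityCurve per VOI
    noisy_tacs: list  # [VOI][scan] TimeActivityCurve
    noise_scales: np.ndarray
    bf: np.ndarray
    ps: np.ndarray
    aath_truth: list  # AATHParameters per VOI
    pct_aif: AttenuationCurve
    pct_tissue: list  # AttenuationCurve per VOI

    def write(self, out_dir) -> Path:
        """Write CSVs plus a manifest; returns the manifest path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.config.seed,
            "truth_model": self.config.truth_model,
            "blood_tac": "blood.csv",
            "tumor_tacs": [],
            "clean_tacs": [],
            "pct_aif": "pct_aif.csv",
            "pct_tissue": [],
            "truth_parameters": [p.as_dict() for p in self.truths],
            "bf": self.bf.tolist(),
            "ps": self.ps.tolist(),
            "noise_scales": self.noise_scales.tolist(),
        }
        write_tac(self.input_fn.tac, out / "blood.csv")
        for j, tac in enumerate(self.clean_tacs):
            name = f"tumor{j:02d}_clean.csv"
            write_tac(tac, out / name)
            manifest["clean_tacs"].append(name)
        for j, scans in enumerate(self.noisy_tacs):
            names = []
            for s, tac in enumerate(scans):
                name = f"tumor{j:02d}_scan{s}.csv"
                write_tac(tac, out / name)
                names.append(name)
            manifest["tumor_tacs"].append(names)
        _write_pct(self.pct_aif, out / "pct_aif.csv")
        for j, curve in enumerate(self.pct_tissue):
            name = f"pct_tumor{j:02d}.csv"
            _write_pct(curve, out / name)
            manifest["pct_tissue"].append(name)
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path


def _write_pct(curve: AttenuationCurve, path):
    import pandas as pd

    pd.DataFrame({"time_s": curve.times_s, "attenuation_hu": curve.values_hu}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_pct(path, label="") -> AttenuationCurve:
    import pandas as pd

    df = pd.read_csv(path)
    return AttenuationCurve(
        df["time_s"].to_numpy(float), df["attenuation_hu"].to_numpy(float), label=label
    )


def sample_truth_params(spec: M.ModelSpec, ranges: dict, rng: np.random.Generator):
    """One truth parameter set drawn uniformly within the configured ranges."""
    free = []
    for name in spec.free_param_names:
        lo, hi = ranges[name.split("-")[0]]
        free.append(rng.uniform(lo, hi))
    return M.KineticParameters.from_free(spec, np.array(free))


def generate_cohort(config: CohortConfig) -> StudyBundle:
    """Generate a full synthetic study from one master seed.

    PET side: truth parameters are sampled within the configured ranges, the
    noise-free TAC is the model curve on the S1 + late-frame schedule, and
    each "scan" adds independent frame-wise Gaussian noise with a per-tumor
    noise scale drawn from the configured (truncated) normal distribution.
    CT side: BF_j = K1_j / E_j with E_j from a sampled PS/BF ratio, so the
    flow-delivery link holds by construction, and tissue curves come from the
    AATH model plus white HU noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spec = M.model_spec(config.truth_model)
    input_fn = generate_input_function()
    tumor_sched = s1_schedule()

    truths, clean, noisy = [], [], []
    scales = np.empty(config.n_tumors)
    bf = np.empty(config.n_tumors)
    ps = np.empty(config.n_tumors)
    aath_truth, pct_tissue = [], []

    t_ct = np.arange(45.0)
    aif_hu = 40.0 + gamma_variate(t_ct)
    aif_hu = aif_hu + rng.normal(0.0, config.pct_noise_sd_hu * 0.2, t_ct.size)
    pct_aif = AttenuationCurve(t_ct, aif_hu, label="aorta")

    for j in range(config.n_tumors):
        p = sample_truth_params(spec, config.truth_ranges, rng)
        truths.append(p)
        tac = M.model_tac(spec, p, input_fn, tumor_sched)
        tac.label = f"tumor{j:02d}"
        clean.append(tac)
        s = rng.normal(config.noise_scale_mean, config.noise_scale_sd)
        s = max(s, config.noise_scale_min)
        scales[j] = s
        noise = NoiseModel(scale=s)
        scans = []
        for k in range(config.n_scans_per_voi):
            sd = noise.frame_sd(tac)
            vals = tac.activity + rng.standard_normal(sd.size) * sd
            scans.append(tac.with_activity(vals, label=f"tumor{j:02d}_scan{k}"))
        noisy.append(scans)

        k1 = p.rates[0]
        ratio = rng.uniform(*config.ps_bf_ratio_range)
        e = -np.expm1(-ratio)
        bf[j] = k1 / e
        ps[j] = ratio * bf[j]
        v_p = rng.uniform(*config.vp_range)
        v_e = rng.uniform(*config.ve_range)
        t0 = rng.uniform(*config.pct_delay_range_s)
        ap = AATHParameters(bf=bf[j], v_p=v_p, v_e=v_e, ps=ps[j], t0_s=t0)
        aath_truth.append(ap)
        tis = 30.0 + aath_tac(ap, t_ct, aif_hu - 40.0, t_ct)
        tis = tis + rng.normal(0.0, config.pct_noise_sd_hu, t_ct.size)
        pct_tissue.append(AttenuationCurve(t_ct, tis, label=f"pct_tumor{j:02d}"))

    return StudyBundle(
        config=config,
        input_fn=input_fn,
        truths=truths,
        clean_tacs=clean,
        noisy_tacs=noisy,
        noise_scales=scales,
        bf=bf,
        ps=ps,
        aath_truth=aath_truth,
        pct_aif=pct_aif,
        pct_tissue=pct_tissue,
    )
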