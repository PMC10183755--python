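"""Synthetic developmental cohorts with the study's statistical structure.

The generator emulates a cross-sectional cohort of 8-18-year-olds:

* demographics and puberty: age uniform on [8, 18]; Pubertal Development
  Scale scores (adrenal PDSA, gonadal PDSG, summary PDSS) follow a
  saturating logistic of age (female onset earlier than male) plus noise
  calibrated so the linear R^2 between age and PDSS is ~0.75 at n = 50;
* regional ground-truth microstructure: per (subject, region) values of
  FA, OD, v_ic, FR, d_a, MTSat anchored at the calibration medians, with
  standardized age, sex, and sex-by-PDSA effects injected on the scale of
  the regional MADs; g-ratio and conduction velocity are derived by the
  voxel-wise algebra, never injected directly;
* voxel samples: per-voxel measure values scattered around the
  subject-region truth with dispersion equal to the regional MAD (the
  empirical voxel spread, which embodies measurement noise);
* voxel signals: forward-model dMRI and FLASH signals with Rician noise
  at a nominal SNR, for exercising the fitting cascade;
* cognition: hit reaction time and d' constructed from age and subject
  mean microstructure with configurable standardized coefficients.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from callosim.schemes import AcquisitionScheme, MPMProtocol, REGION_ORDER
from callosim.signals import (
    DiameterDistribution,
    MicrostructureParams,
    axcaliber_signal,
    noddi_signal,
    kappa_from_od,
)
from callosim.mpm import simulate_mpm_voxel
from callosim.gratio import mvf, avf_noddi, g_ratio, conduction_velocity

PRIMITIVE_MEASURES = ("fa", "od", "vic", "fr", "da", "mtsat")
DERIVED_MEASURES = ("g", "cv")

_CLIP_RANGES = {
    "fa": (0.05, 0.99),
    "od": (0.003, 0.9),
    "vic": (0.05, 0.95),
    "fr": (0.05, 0.95),
    "da": (0.5, 15.0),
    "mtsat": (0.5, 8.5),
}


class ConfigurationError(ValueError):
    pass


def load_calibration():
    """Regional medians/MADs shipped as package data."""
    with resources.files("callosim.data").joinpath("regional_calibration.csv").open() as fh:
        return pd.read_csv(fh)


def load_effects():
    """Default standardized effect coefficients per measure and region."""
    with resources.files("callosim.data").joinpath("regional_effects.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class CohortConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    n_subjects: int = 50
    age_range: tuple = (8.0, 18.0)
    p_female: float = 0.6
    # puberty: logistic onset age (years); female earlier than male
    pds_onset_female: float = 11.5
    sex_onset_offset: float = 1.0            # male onset delay, years
    pds_scale: float = 1.5                   # logistic width, years
    pds_noise_sd: float = 0.5                # score units
    adrenal_onset_shift: float = -0.5        # adrenarche precedes gonadarche
    gonadal_onset_shift: float = 0.3
    # BMI calibration (kg/m^2)
    bmi_intercept: float = 19.87
    bmi_age_slope: float = 0.57
    bmi_noise_sd: float = 2.71
    # microstructure truth
    subject_sd: float = 0.5          # between-subject SD, units of regional MAD
    subject_region_sd: float = 0.25  # subject-by-region SD, units of MAD
    voxel_noise_scale: float = 1.0   # voxel SD as multiple of regional MAD
    v_iso: float = 0.02
    effect_scale: float = 1.0    # global multiplier on injected effects
    # signal synthesis
    snr: float = 30.0
    A_flash: float = 1000.0
    ec_disorder_A: float = 0.8   # extracellular disorder amplitude (um^2)
    gamma_shape: float = 3.0     # shape of the generating gamma distribution
    # cognition (standardized coefficients)
    beta_rt_age: float = -0.45
    beta_rt_da: float = -0.63
    rt_noise_sd: float = 0.45
    beta_dp_mtsat: float = 0.57
    beta_dp_g: float = -0.48
    dp_noise_sd: float = 0.55
    rt_mean: float = 1102.0
    rt_sd: float = 236.0
    dp_mean: float = 1.99
    dp_sd: float = 0.81
    n_cognition: int | None = None   # None = full cohort

    def __post_init__(self):
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must be increasing")
        if not 0.0 <= self.p_female <= 1.0:
            raise ConfigurationError("p_female must lie in [0, 1]")
        for name in ("pds_scale", "pds_noise_sd", "bmi_noise_sd", "subject_sd",
                     "voxel_noise_scale", "snr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.v_iso < 1.0:
            raise ConfigurationError("v_iso must lie in [0, 1)")

    def replace(self, **kw):
        return replace(self, **kw)


def _logistic_pds(age, onset, scale):
    return 1.0 + 3.0 / (1.0 + np.exp(-(age - onset) / scale))


def generate_cohort(n, seed, config: CohortConfig | None = None) -> pd.DataFrame:
    """Subject table: id, age, sex, PDSA/PDSG/PDSS, BMI, pubertal status."""
    if n < 2:
        raise ConfigurationError("need n >= 2 subjects")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    age = rng.uniform(*cfg.age_range, size=n)
    female = rng.random(n) < cfg.p_female
    onset = np.where(female, cfg.pds_onset_female,
                     cfg.pds_onset_female + cfg.sex_onset_offset)

    def score(shift):
        latent = _logistic_pds(age, onset + shift, cfg.pds_scale)
        return np.clip(latent + rng.normal(0, cfg.pds_noise_sd, n), 1.0, 4.0)

    pdss = score(0.0)
    pdsa = score(cfg.adrenal_onset_shift)
    pdsg = score(cfg.gonadal_onset_shift)
    bmi = (cfg.bmi_intercept + cfg.bmi_age_slope * (age - np.mean(cfg.age_range))
           + rng.normal(0, cfg.bmi_noise_sd, n))
    return pd.DataFrame({
        "subject": [f"S{i + 1:03d}" for i in range(n)],
        "age": age,
        "sex": np.where(female, "F", "M"),
        "PDSA": pdsa,
        "PDSG": pdsg,
        "PDSS": pdss,
        "BMI": bmi,
        "pubertal_status": np.where(pdss < 1.5, "prepubertal", "pubertal"),
    })


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_truth_table(profiles: pd.DataFrame, seed,
                         config: CohortConfig | None = None,
                         effects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (subject, region) ground-truth measures.

    Truth = regional median + MAD * (beta_age z_age + beta_sex male
    + beta_sexpdsa male z_PDSA + subject effect + subject-region effect):
    the subject effect is shared across regions within a measure (a genuine
    random intercept) and the subject-region effect adds independent
    anatomical variation per region.  g and cv are derived from the
    primitive truths voxel-algebra style.
    """
    cfg = config or CohortConfig()
    cal = load_calibration().set_index(["region", "measure"])
    eff = (effects if effects is not None else load_effects()).set_index(
        ["measure", "region"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    z_age = _zscore(profiles["age"])
    z_pdsa = _zscore(profiles["PDSA"])
    male = (profiles["sex"] == "M").to_numpy(dtype=float)
    n = len(profiles)
    u = {m: rng.normal(0, cfg.subject_sd, n) for m in PRIMITIVE_MEASURES}
    rows = []
    for region in REGION_ORDER:
        rec = {"region": region, "subject": profiles["subject"].to_numpy()}
        for m in PRIMITIVE_MEASURES:
            med = cal.loc[(region, m), "median"]
            mad = cal.loc[(region, m), "mad"]
            try:
                e = eff.loc[(m, region)]
                ba, bs, bi = (e["beta_age"], e["beta_sex"], e["beta_sex_pdsa"])
            except KeyError:
                ba = bs = bi = 0.0
            u_sr = rng.normal(0, cfg.subject_region_sd, n)
            shift = cfg.effect_scale * (ba * z_age + bs * male
                                        + bi * male * z_pdsa) + u[m] + u_sr
            val = med + mad * shift
            rec[m] = np.clip(val, *_CLIP_RANGES[m])
        rows.append(pd.DataFrame(rec))
    truth = pd.concat(rows, ignore_index=True)
    truth = derive_gratio_cv(truth, v_iso=cfg.v_iso)
    return truth


def generate_region_truth(profile, region, seed,
                          config: CohortConfig | None = None) -> dict:
    """Single (subject, region) truth record; thin wrapper over
    :func:`generate_truth_table` semantics for one-off use."""
    if region not in REGION_ORDER:
        raise ValueError(f"unknown region {region!r}")
    profiles = pd.DataFrame([dict(profile)])
    if len(profiles) == 1:
        # a single subject has no cohort z-scores; treat it as the center
        cfg = config or CohortConfig()
        cal = load_calibration().set_index(["region", "measure"])
        rec = {"subject": profiles.loc[0, "subject"], "region": region}
        for m in PRIMITIVE_MEASURES:
            rec[m] = cal.loc[(region, m), "median"]
        mv = mvf(rec["mtsat"])
        rec["g"] = g_ratio(mv, avf_noddi(mv, cfg.v_iso, rec["vic"]))
        rec["cv"] = conduction_velocity(rec["da"], rec["g"])
        return rec
    raise ValueError("pass one subject profile")


def derive_gratio_cv(table: pd.DataFrame, v_iso=0.02) -> pd.DataFrame:
    """Add voxel-wise g-ratio (NODDI AVF route) and conduction velocity
    columns derived from mtsat, vic, and da."""
    out = table.copy()
    mv = mvf(out["mtsat"].to_numpy())
    avf = avf_noddi(mv, v_iso, out["vic"].to_numpy())
    out["g"] = g_ratio(mv, avf)
    out["cv"] = conduction_velocity(out["da"].to_numpy(), out["g"].to_numpy())
    return out


def generate_voxel_measures(truth: pd.DataFrame, n_voxels, seed,
                            config: CohortConfig | None = None,
                            include_derived=True) -> pd.DataFrame:
    """Long voxel-measure table: (subject, region, voxel, measure, value).

    Voxel values scatter around the subject-region truth with SD equal to
    the regional MAD (times ``voxel_noise_scale``).  g and cv are computed
    per voxel from the sampled primitives when ``include_derived``.
    """
    cfg = config or CohortConfig()
    cal = load_calibration().set_index(["region", "measure"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    reps = truth.loc[truth.index.repeat(n_voxels)].reset_index(drop=True)
    reps["voxel"] = np.tile(np.arange(n_voxels), len(truth))
    for m in PRIMITIVE_MEASURES:
        mad = reps["region"].map(
            {r: cal.loc[(r, m), "mad"] for r in REGION_ORDER}
        ).to_numpy()
        noise = rng.normal(0, 1.0, len(reps)) * mad * cfg.voxel_noise_scale
        reps[m] = np.clip(reps[m].to_numpy() + noise, *_CLIP_RANGES[m])
    cols = ["subject", "region", "voxel", *PRIMITIVE_MEASURES]
    out = reps[cols]
    if include_derived:
        out = derive_gratio_cv(out, v_iso=cfg.v_iso)
    return out.melt(id_vars=["subject", "region", "voxel"],
                    var_name="measure", value_name="value")


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def rician_noise(signal, sigma, rng):
    """Magnitude of a complex Gaussian perturbation: |S + e1 + i e2|."""
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    e1 = rng.normal(0, sigma, signal.shape)
    e2 = rng.normal(0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def truth_to_params(rec, config: CohortConfig | None = None,
                    orientation=(0.0, 0.0, 1.0)) -> MicrostructureParams:
    """Microstructure parameters for forward simulation from a truth
    record (mapping with fr, da, vic, od, mtsat)."""
    cfg = config or CohortConfig()
    dist = DiameterDistribution("gamma", k=cfg.gamma_shape,
                                theta=float(rec["da"]) / cfg.gamma_shape)
    return MicrostructureParams(
        fr=float(rec["fr"]), dist=dist, A=cfg.ec_disorder_A,
        orientation=np.asarray(orientation, dtype=float),
        v_ic=float(rec["vic"]), v_iso=cfg.v_iso,
        kappa=kappa_from_od(float(np.clip(rec["od"], 1e-3, 0.99))),
        mtsat=float(rec["mtsat"]),
    )


def synthesize_signals(params: MicrostructureParams,
                       schemes: dict[str, AcquisitionScheme],
                       mpm_protocol: MPMProtocol | None = None,
                       snr=30.0, seed=0, n_voxels=1) -> dict:
    """Forward-simulate voxel signal sets with Rician noise.

    ``schemes`` maps names to acquisition schemes; key ``"protocol1"`` (if
    present) is simulated with the NODDI forward model and every other key
    with the AxCaliber (distribution + time-dependent zeppelin) model.
    FLASH triplets are simulated when ``mpm_protocol`` is given, with
    noise SD = S_PD / snr.  ``snr=np.inf`` gives noise-free signals.

    Returns {name: (n_voxels, n_volumes) array, "mpm": (n_voxels, 3)}.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0 (np.inf for noise-free)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    out = {}
    for name, scheme in schemes.items():
        if name == "protocol1":
            clean = noddi_signal(scheme, params)
        else:
            clean = axcaliber_signal(scheme, params)
        stack = np.tile(clean, (n_voxels, 1))
        out[name] = rician_noise(stack, sigma, rng)
    if mpm_protocol is not None:
        cfg = CohortConfig()
        mtsat = params.mtsat if params.mtsat is not None else 3.5
        r1 = 0.6 + 0.1 * mtsat
        s = np.array(simulate_mpm_voxel(cfg.A_flash, r1, mtsat, mpm_protocol))
        stack = np.tile(s, (n_voxels, 1))
        sig = 0.0 if np.isinf(snr) else s[1] / snr
        out["mpm"] = rician_noise(stack, sig, rng)
    return out


def generate_cognition(profiles: pd.DataFrame, truth: pd.DataFrame, seed,
                       config: CohortConfig | None = None) -> pd.DataFrame:
    """Attach hit reaction time (ms) and d' to the subject table.

    hit RT is linear in age and standardized subject-mean d_a (default
    standardized coefficient -0.63: larger axons, faster processing);
    d' is linear in standardized MTSat (+0.57) and g-ratio (-0.48).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    sub = truth.groupby("subject")[["da", "mtsat", "g"]].mean()
    sub = sub.loc[profiles["subject"]]
    z_age = _zscore(profiles["age"])
    z_da = _zscore(sub["da"])
    z_mt = _zscore(sub["mtsat"])
    z_g = _zscore(sub["g"])
    n = len(profiles)
    z_rt = (cfg.beta_rt_age * z_age + cfg.beta_rt_da * z_da
            + rng.normal(0, cfg.rt_noise_sd, n))
    z_dp = (cfg.beta_dp_mtsat * z_mt + cfg.beta_dp_g * z_g
            + rng.normal(0, cfg.dp_noise_sd, n))
    out = profiles.copy()
    out["hit_rt"] = cfg.rt_mean + cfg.rt_sd * np.asarray(z_rt)
    out["d_prime"] = cfg.dp_mean + cfg.dp_sd * np.asarray(z_dp)
    if cfg.n_cognition is not None and cfg.n_cognition < n:
        keep = rng.choice(n, size=cfg.n_cognition, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[keep] = True
        out.loc[~mask, ["hit_rt", "d_prime"]] = np.nan
    return out


def generate_cohort_dataset(n, seed, n_voxels=50,
                            config: CohortConfig | None = None) -> dict:
    """Full synthetic dataset: subject profiles (with cognition), truth
    table, and long voxel-measure table."""
    cfg = config or CohortConfig()
    profiles = generate_cohort(n, seed, cfg)
    truth = generate_truth_table(profiles, seed, cfg)
    profiles = generate_cognition(profiles, truth, seed, cfg)
    voxels = generate_voxel_measures(truth, n_voxels, seed, cfg)
    return {"profiles": profiles, "truth": truth, "voxels": voxels}
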