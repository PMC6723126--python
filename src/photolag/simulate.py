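"""Synthetic transcript/protein time-course data with ground truth.

The generator draws per-gene kinetic parameters (one of four regulation
classes), evaluates the noise-free pulse-response trajectories at the design
time points, and layers on measurement noise that mimics the two assay
platforms:

* transcript counts: negative-binomial around library-size-scaled means;
* protein reporter intensities: multiplicative log-normal noise plus a
  per-run (batch) offset on the log2 scale, with whole-run detection
  failures whose probability decreases with protein abundance.

Each gene owns an independent RNG substream keyed by ``(seed, stream,
class, index)``, so enlarging one class never perturbs the values drawn for
existing genes, and the kinetic parameters of a dataset are reproducible
with noise disabled (the "noise-free twin" used for ground-truth checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import PulseDesign
from .kinetics import REG_CLASSES, KineticGene, mrna_trajectory, protein_trajectory
from .matrix import AbundanceMatrix, sample_table

_LN2 = math.log(2.0)

# substream tags
_PARAMS, _NOISE, _SAMPLES = 1, 2, 3
_CLASS_CODE = {cls: i for i, cls in enumerate(REG_CLASSES)}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for both layers.

    ``nb_dispersion`` is the negative-binomial dispersion (variance =
    mu + dispersion * mu^2); 0 disables count noise entirely and returns the
    exact means.  ``lognormal_sigma`` is the sd of multiplicative protein
    noise on the natural-log scale.  ``batch_offsets`` are per-run additive
    offsets in log2 units (None: drawn once per dataset, N(0, batch_sd)).
    ``missing_logistic = (intercept, slope)`` sets the whole-run detection
    failure probability expit(intercept - slope * log2(abundance)); None
    disables missingness.  ``library_sizes`` are per-transcript-sample
    scaling factors (None: drawn log-normal with sd ``library_log_sd``).
    """

    nb_dispersion: float = 0.02
    lognormal_sigma: float = 0.15
    batch_offsets: tuple[float, ...] | None = None
    batch_sd: float = 0.3
    missing_logistic: tuple[float, float] | None = (8.4, 0.8)
    library_sizes: tuple[float, ...] | None = None
    library_log_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if self.missing_logistic is not None and len(self.missing_logistic) != 2:
            raise ValueError("missing_logistic must be (intercept, slope)")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(
            nb_dispersion=0.0,
            lognormal_sigma=0.0,
            batch_offsets=(),
            batch_sd=0.0,
            missing_logistic=None,
            library_sizes=(),
            library_log_sd=0.0,
        )

    def to_dict(self) -> dict:
        return {
            "nb_dispersion": self.nb_dispersion,
            "lognormal_sigma": self.lognormal_sigma,
            "batch_offsets": None if self.batch_offsets is None else list(self.batch_offsets),
            "batch_sd": self.batch_sd,
            "missing_logistic": None if self.missing_logistic is None else list(self.missing_logistic),
            "library_sizes": None if self.library_sizes is None else list(self.library_sizes),
            "library_log_sd": self.library_log_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        d = dict(d)
        for key in ("batch_offsets", "missing_logistic", "library_sizes"):
            if d.get(key) is not None:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


@dataclass(frozen=True)
class GenePriors:
    """Per-class parameter distributions for drawn genes.

    Defaults place noise-free mRNA peaks 3-23-fold above baseline within
    ~15-40 min of the pulse and protein peaks 2-8-fold near 115-235 min,
    the response envelope of a short-pulse light experiment.
    """

    alpha_range: tuple[float, float] = (0.5, 20.0)     # basal transcription, a.u./min
    beta_range: tuple[float, float] = (12.0, 40.0)     # induced fold-increase
    induction_tau_range: tuple[float, float] = (15.0, 60.0)  # signal persistence, min
    delta_m_mean: float = _LN2 / 20.0                  # 20-min mRNA half-life
    delta_p_mean: float = _LN2 / 120.0                 # 120-min protein half-life
    rate_log_sd: float = 0.2                           # lognormal jitter on decay rates
    k_s: float = 1.0
    attenuation: float = 0.3                           # buffered-class translation cut
    attenuation_tau: float = math.inf                  # inf: permanent cut
    protein_boost_range: tuple[float, float] = (4.0, 10.0)

    def to_dict(self) -> dict:
        return {
            "alpha_range": list(self.alpha_range),
            "beta_range": list(self.beta_range),
            "induction_tau_range": list(self.induction_tau_range),
            "delta_m_mean": self.delta_m_mean,
            "delta_p_mean": self.delta_p_mean,
            "rate_log_sd": self.rate_log_sd,
            "k_s": self.k_s,
            "attenuation": self.attenuation,
            "attenuation_tau": self.attenuation_tau,
            "protein_boost_range": list(self.protein_boost_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenePriors":
        d = dict(d)
        for key in ("alpha_range", "beta_range", "induction_tau_range", "protein_boost_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        if d.get("attenuation_tau") in (None, "inf"):
            d["attenuation_tau"] = math.inf
        return cls(**d)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def draw_gene(
    reg_class: str, index: int, seed: int, priors: GenePriors = GenePriors()
) -> KineticGene:
    """Draw one gene's kinetic parameters from its class-keyed substream."""
    rng = np.random.default_rng([seed, _PARAMS, _CLASS_CODE[reg_class], index])
    alpha = _loguniform(rng, *priors.alpha_range)
    delta_m = priors.delta_m_mean * float(np.exp(rng.normal(0.0, priors.rate_log_sd)))
    delta_p = priors.delta_p_mean * float(np.exp(rng.normal(0.0, priors.rate_log_sd)))
    beta, tau_i, att, boost = 0.0, 0.0, 1.0, 1.0
    if reg_class in ("concordant", "transcript_only"):
        beta = _loguniform(rng, *priors.beta_range)
        tau_i = _loguniform(rng, *priors.induction_tau_range)
    if reg_class == "transcript_only":
        att = priors.attenuation
    if reg_class == "protein_only":
        boost = _loguniform(rng, *priors.protein_boost_range)
    return KineticGene(
        gene_id=f"g_{reg_class}_{index:05d}",
        reg_class=reg_class,
        alpha=alpha,
        beta=beta,
        delta_m=delta_m,
        k_s=priors.k_s,
        delta_p=delta_p,
        attenuation=att,
        protein_boost=boost,
        induction_tau=tau_i,
        attenuation_tau=priors.attenuation_tau,
    )


def _normalize_classes(n_per_class: dict) -> dict[str, int]:
    # YAML reads a bare `null:` key as None; map it back to the class name
    return {("null" if cls is None else cls): n for cls, n in n_per_class.items()}


def draw_genes(
    n_per_class: dict[str, int], seed: int, priors: GenePriors = GenePriors()
) -> list[KineticGene]:
    n_per_class = _normalize_classes(n_per_class)
    for cls, n in n_per_class.items():
        if cls not in REG_CLASSES:
            raise ValueError(f"unknown regulation class {cls!r}")
        if n < 0:
            raise ValueError("gene counts must be >= 0")
    genes: list[KineticGene] = []
    for cls in REG_CLASSES:  # fixed class order for stable ids
        for i in range(n_per_class.get(cls, 0)):
            genes.append(draw_gene(cls, i, seed, priors))
    return genes


@dataclass
class SyntheticDataset:
    """Generated two-layer dataset plus everything needed to reproduce it."""

    transcripts: AbundanceMatrix
    proteins: AbundanceMatrix
    truth: pd.DataFrame
    design: PulseDesign
    noise: NoiseModel
    seed: int
    library_sizes: pd.Series
    batch_offsets: pd.Series

    def write(self, outdir) -> dict[str, str]:
        """Write TSV matrices, ground truth and a JSON manifest; return paths."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": str(outdir / "transcripts.tsv"),
            "transcript_samples": str(outdir / "transcript_samples.tsv"),
            "proteins": str(outdir / "proteins.tsv"),
            "protein_samples": str(outdir / "protein_samples.tsv"),
            "truth": str(outdir / "ground_truth.tsv"),
            "manifest": str(outdir / "simulation_manifest.json"),
        }
        self.transcripts.write_tsv(paths["transcripts"], paths["transcript_samples"])
        self.proteins.write_tsv(paths["proteins"], paths["protein_samples"])
        truth = self.truth.copy()
        truth.to_csv(paths["truth"], sep="\t", index=False)
        manifest = {
            "design": self.design.to_dict(),
            "noise": self.noise.to_dict(),
            "seed": self.seed,
            "library_sizes": {k: float(v) for k, v in self.library_sizes.items()},
            "batch_offsets": {k: float(v) for k, v in self.batch_offsets.items()},
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        return paths


def _truth_table(genes: list[KineticGene]) -> pd.DataFrame:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "reg_class": g.reg_class,
                "alpha": g.alpha,
                "beta": g.beta,
                "delta_m": g.delta_m,
                "k_s": g.k_s,
                "delta_p": g.delta_p,
                "attenuation": g.attenuation,
                "protein_boost": g.protein_boost,
                "induction_tau": g.induction_tau,
                "attenuation_tau": g.attenuation_tau,
                "mrna_baseline": g.mrna_baseline,
                "protein_baseline": g.protein_baseline,
            }
        )
    return pd.DataFrame(rows)


def generate_dataset(
    n_per_class: dict[str, int],
    design: PulseDesign | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    priors: GenePriors = GenePriors(),
) -> SyntheticDataset:
    """Generate matched transcript and protein matrices with ground truth.

    Identical arguments (including seed) give bit-identical output.  The
    protein layer may contain whole-run missing values; the transcript layer
    never does.
    """
    design = design or PulseDesign()
    noise = noise if noise is not None else NoiseModel()
    seed = design.seed if seed is None else seed

    genes = draw_genes(n_per_class, seed, priors)
    t_samples = sample_table(design, "transcript")
    p_samples = sample_table(design, "protein")
    n_rep = design.n_replicates

    # dataset-level draws (library sizes, batch offsets)
    rng_ds = np.random.default_rng([seed, _SAMPLES])
    if noise.library_sizes is not None and len(noise.library_sizes) == len(t_samples):
        lib = np.asarray(noise.library_sizes, dtype=float)
    elif noise.library_sizes is not None and len(noise.library_sizes) == 0:
        lib = np.ones(len(t_samples))
    elif noise.library_sizes is None:
        lib = np.exp(rng_ds.normal(0.0, noise.library_log_sd, size=len(t_samples)))
    else:
        raise ValueError("library_sizes length must match transcript sample count")
    if noise.batch_offsets is not None and len(noise.batch_offsets) == n_rep:
        batch = np.asarray(noise.batch_offsets, dtype=float)
    elif noise.batch_offsets is not None and len(noise.batch_offsets) == 0:
        batch = np.zeros(n_rep)
    elif noise.batch_offsets is None:
        batch = rng_ds.normal(0.0, noise.batch_sd, size=n_rep)
    else:
        raise ValueError("batch_offsets length must match n_replicates")

    t_times = np.array(
        [0.0 if c else m for c, m in zip(t_samples["is_control"], t_samples["minutes"])]
    )
    p_times = np.array(
        [0.0 if c else m for c, m in zip(p_samples["is_control"], p_samples["minutes"])]
    )
    t_ctrl = t_samples["is_control"].to_numpy()
    p_ctrl = p_samples["is_control"].to_numpy()
    p_batch_idx = (p_samples["replicate"].to_numpy() - 1).astype(int)

    t_rows = np.empty((len(genes), len(t_samples)))
    p_rows = np.empty((len(genes), len(p_samples)))
    for gi, g in enumerate(genes):
        rng = np.random.default_rng([seed, _NOISE, _CLASS_CODE[g.reg_class],
                                     int(g.gene_id.rsplit("_", 1)[1])])
        m_vals = np.where(t_ctrl, g.mrna_baseline, mrna_trajectory(g, design, t_times))
        mu = m_vals * lib
        if noise.nb_dispersion > 0:
            size = 1.0 / noise.nb_dispersion
            t_rows[gi] = rng.negative_binomial(size, size / (size + mu))
        else:
            t_rows[gi] = mu

        p_vals = np.where(p_ctrl, g.protein_baseline, protein_trajectory(g, design, p_times))
        intensity = p_vals * np.exp2(batch[p_batch_idx])
        if noise.lognormal_sigma > 0:
            intensity = intensity * np.exp(
                rng.normal(0.0, noise.lognormal_sigma, size=len(p_vals))
            )
        if noise.missing_logistic is not None:
            icpt, slope = noise.missing_logistic
            run_abund = np.log2(g.protein_baseline) + batch
            p_miss = expit(icpt - slope * run_abund)
            miss_run = rng.random(n_rep) < p_miss
            intensity = np.where(miss_run[p_batch_idx], np.nan, intensity)
        p_rows[gi] = intensity

    ids = [g.gene_id for g in genes]
    transcripts = AbundanceMatrix(
        values=pd.DataFrame(t_rows, index=pd.Index(ids, name="feature_id"),
                            columns=t_samples.index),
        samples=t_samples,
        layer="transcript",
    )
    proteins = AbundanceMatrix(
        values=pd.DataFrame(p_rows, index=pd.Index(ids, name="feature_id"),
                            columns=p_samples.index),
        samples=p_samples,
        layer="protein",
    )
    return SyntheticDataset(
        transcripts=transcripts,
        proteins=proteins,
        truth=_truth_table(genes),
        design=design,
        noise=noise,
        seed=seed,
        library_sizes=pd.Series(lib, index=t_samples.index, name="library_size"),
        batch_offsets=pd.Series(batch, index=[f"R{r}" for r in range(1, n_rep + 1)],
                                name="batch_log2_offset"),
    )
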