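"""Synthetic paired call sets with known error mechanisms.

The generator draws truth genotypes under Hardy-Weinberg equilibrium
(per-SNP minor-allele frequency q gives genotype probabilities
(1-q)^2, 2q(1-q), q^2), then produces each platform's observed calls by
pushing the truth through a 3x3 row-stochastic confusion matrix over
{AA, AB, BB} and masking calls to missing at a platform-specific rate.
The error process can optionally depend on MAF (a multiplier on the
off-diagonal error mass) and on a binary phenotype (separate confusion
matrices per group — the differential-error mechanism that inflates
type I error downstream).  Because both platforms observe the *same*
truth, every concordance statistic the pipeline reports has a known
expectation in terms of the configured matrices, which is what makes
end-to-end parameter-recovery tests possible.

Default dimensions mirror the dual-platform hypertension study the
pipeline is modelled on: 959 samples of which 464 are directly
sequenced and 495 imputed, common SNPs (MAF uniform on [0.05, 0.5]),
a sequence platform with ~2.4% missingness and a near-complete
microarray, and small adjacent-class call-error rates giving ~0.2%
called discordance.

Reproducibility: one global integer seed; every stream derives its
generator as ``default_rng([seed, STREAM_ID])`` with fixed per-purpose
stream ids, so regenerating any one piece is stable regardless of call
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from gtconcord.calls import XX
from gtconcord.differential import PhenotypeTable
from gtconcord.genio import GenotypeMatrix, HarmonizedPair, harmonize

# fixed per-purpose stream ids for default_rng([seed, stream_id])
STREAM_VARIANTS = 0
STREAM_TRUTH = 1
STREAM_SEQ = 2
STREAM_MICRO = 3
STREAM_PHENO = 4
STREAM_MAF = 5

_ODD_AUTOSOMES = [str(c) for c in range(1, 22, 2)]


def _default_seq_errors() -> np.ndarray:
    # adjacent-class errors dominate; hom-hom flips are rare
    return np.array([[0.9980, 0.0018, 0.0002],
                     [0.0015, 0.9970, 0.0015],
                     [0.0002, 0.0018, 0.9980]])


def _default_micro_errors() -> np.ndarray:
    return np.array([[0.9995, 0.0004, 0.0001],
                     [0.0004, 0.9992, 0.0004],
                     [0.0001, 0.0004, 0.9995]])


@dataclass
class PlatformConfig:
    """Error mechanism of one genotyping platform.

    ``error_matrix[g, h]`` = P(observed call h | true genotype g) over
    (AA, AB, BB); rows must sum to 1.  ``missing_rate`` masks observed
    calls to XX independently of the call error.  ``maf_dependence``
    maps a SNP's MAF to a multiplier on the off-diagonal error mass
    (e.g. ``lambda q: 0.05 / q`` for inverse-MAF error).
    ``differential`` supplies per-group confusion matrices keyed by a
    binary phenotype (group 0, group 1) and overrides ``error_matrix``.
    """

    error_matrix: np.ndarray = field(default_factory=_default_seq_errors)
    missing_rate: float = 0.0
    maf_dependence: Optional[Callable[[float], float]] = None
    differential: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.error_matrix = _check_error_matrix(self.error_matrix)
        if self.differential is not None:
            self.differential = tuple(  # type: ignore[assignment]
                _check_error_matrix(m) for m in self.differential)
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


def _check_error_matrix(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("error matrix must be 3x3 over (AA, AB, BB)")
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("error matrix rows must be non-negative and sum to 1")
    return m


MafSpec = Union[float, tuple, Sequence[float], np.ndarray]


@dataclass
class SimulationConfig:
    """Full specification of a simulated dual-platform study."""

    n_snps: int = 1000
    n_samples: int = 959
    maf_spec: MafSpec = (0.05, 0.5)
    seq: PlatformConfig = field(default_factory=lambda: PlatformConfig(
        _default_seq_errors(), missing_rate=0.024))
    micro: PlatformConfig = field(default_factory=lambda: PlatformConfig(
        _default_micro_errors(), missing_rate=0.0002))
    phenotype_prevalence: float = 0.30
    smoking_prevalence: float = 0.25
    n_ngs: Optional[int] = None   # default: 464/959 of the samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_samples < 1:
            raise ValueError("n_snps and n_samples must be positive")
        if not 0.0 < self.phenotype_prevalence < 1.0:
            raise ValueError("phenotype_prevalence must be in (0, 1)")
        if self.n_ngs is None:
            self.n_ngs = int(round(self.n_samples * 464 / 959))
        if not 0 <= self.n_ngs <= self.n_samples:
            raise ValueError("n_ngs must be in [0, n_samples]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def mafs(self) -> np.ndarray:
        """Resolve maf_spec into one MAF per SNP (deterministic per seed)."""
        spec = self.maf_spec
        rng = self.rng(STREAM_MAF)
        if np.isscalar(spec):
            q = np.full(self.n_snps, float(spec))
        elif isinstance(spec, tuple) and len(spec) == 2:
            lo, hi = map(float, spec)
            q = rng.uniform(lo, hi, self.n_snps)
        else:
            vals = np.asarray(spec, dtype=float)
            q = (vals if len(vals) == self.n_snps
                 else rng.choice(vals, self.n_snps, replace=True))
        if (q < 0).any() or (q > 0.5).any():
            raise ValueError("MAF values must lie in [0, 0.5]")
        return q


def _variant_table(cfg: SimulationConfig) -> pd.DataFrame:
    rng = cfg.rng(STREAM_VARIANTS)
    chrom = [_ODD_AUTOSOMES[i % len(_ODD_AUTOSOMES)] for i in range(cfg.n_snps)]
    alleles = np.array(list("ACGT"))
    pairs = [rng.choice(4, size=2, replace=False) for _ in range(cfg.n_snps)]
    return pd.DataFrame({
        "rs_id": [f"rs{i + 1}" for i in range(cfg.n_snps)],
        "chrom": chrom,
        "pos": np.arange(1, cfg.n_snps + 1) * 1000,
        "allele_major": [alleles[p[0]] for p in pairs],
        "allele_minor": [alleles[p[1]] for p in pairs],
    })


def simulate_truth(cfg: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg truth genotypes: P(AA,AB,BB) = ((1-q)^2, 2q(1-q), q^2).

    Genotypes are i.i.d. across samples given each SNP's MAF; no linkage
    disequilibrium or pedigree structure is simulated.  Fully
    deterministic under the config seed.
    """
    q = cfg.mafs()
    probs = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)
    cum = np.cumsum(probs, axis=1)
    rng = cfg.rng(STREAM_TRUTH)
    u = rng.uniform(size=(cfg.n_snps, cfg.n_samples))
    calls = (u[:, :, None] >= cum[:, None, :2]).sum(axis=2).astype(np.int8)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(_variant_table(cfg), samples, calls)


def simulate_platform_calls(truth: GenotypeMatrix, platform: PlatformConfig,
                            stream: int, cfg: SimulationConfig,
                            phenotype: Optional[np.ndarray] = None,
                            mafs: Optional[np.ndarray] = None,
                            ) -> GenotypeMatrix:
    """Push truth genotypes through one platform's error mechanism.

    Each true call is perturbed by the confusion matrix — group-specific
    in differential mode, off-diagonal mass scaled by
    ``maf_dependence(q)`` when set — then masked to XX with the
    platform's missing rate.  ``stream`` selects the platform's RNG
    stream (STREAM_SEQ / STREAM_MICRO) so the two platforms' errors are
    independent but individually reproducible.
    """
    n_snps, n_samples = truth.n_variants, truth.n_samples
    if platform.differential is not None:
        if phenotype is None:
            raise ValueError("differential error mode requires phenotype labels")
        phenotype = np.asarray(phenotype, dtype=np.int64)
        if phenotype.shape != (n_samples,) or not np.isin(phenotype, [0, 1]).all():
            raise ValueError("phenotype labels must be 0/1 per sample")
        group_mats = platform.differential
        groups = (phenotype == 0, phenotype == 1)
    else:
        group_mats = (platform.error_matrix,)
        groups = (np.ones(n_samples, dtype=bool),)

    if platform.maf_dependence is not None:
        if mafs is None:
            mafs = cfg.mafs()
        mult = np.array([float(platform.maf_dependence(q)) for q in mafs])
    else:
        mult = np.ones(n_snps)

    rng = cfg.rng(stream)
    u_err = rng.uniform(size=(n_snps, n_samples))
    u_miss = rng.uniform(size=(n_snps, n_samples))

    calls = np.empty((n_snps, n_samples), dtype=np.int8)
    for mat, in_group in zip(group_mats, groups):
        # per-SNP matrices: off-diagonal mass scaled, diagonal re-normalised
        off = mat - np.diag(np.diag(mat))
        scaled = off[None, :, :] * mult[:, None, None]
        diag = 1.0 - scaled.sum(axis=2)
        if (diag < -1e-12).any():
            raise ValueError("maf_dependence multiplier makes error mass > 1")
        per_snp = scaled + np.einsum("sg,gh->sgh", diag, np.eye(3))
        cum = np.cumsum(per_snp, axis=2)  # (n_snps, 3, 3)
        for g in range(3):
            mask = (truth.calls == g) & in_group[None, :]
            if not mask.any():
                continue
            si = np.nonzero(mask)[0]
            thresholds = cum[si, g, :2]  # (n_cells, 2)
            calls[mask] = (u_err[mask][:, None] >= thresholds).sum(axis=1)
    calls[u_miss < platform.missing_rate] = XX
    return GenotypeMatrix(truth.variants, truth.samples, calls)


def simulate_phenotypes(cfg: SimulationConfig) -> PhenotypeTable:
    """Binary phenotype labels with raw records that re-derive exactly.

    The primary label is 'hypertensive' at the configured prevalence:
    affected samples get at least one of four exams with systolic
    pressure above 140 mm Hg, unaffected samples stay at or below
    140/90 on every exam, so :func:`~gtconcord.differential.
    derive_hypertension` round-trips the generated labels.  Smoking
    waves behave analogously; sex is balanced; sequence source assigns
    ``n_ngs`` samples to direct sequencing and the rest to imputation,
    in a seeded random order.
    """
    rng = cfg.rng(STREAM_PHENO)
    n = cfg.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    hyper = rng.uniform(size=n) < cfg.phenotype_prevalence
    if not 0.0 < cfg.smoking_prevalence < 1.0:
        raise ValueError("smoking_prevalence must be in (0, 1)")
    smoker = rng.uniform(size=n) < cfg.smoking_prevalence

    sbp = np.round(rng.uniform(100.0, 138.0, size=(n, 4)), 1)
    dbp = np.round(rng.uniform(60.0, 88.0, size=(n, 4)), 1)
    hot_exam = rng.integers(0, 4, size=n)
    hi_sbp = np.round(rng.uniform(141.0, 185.0, size=n), 1)
    idx = np.nonzero(hyper)[0]
    sbp[idx, hot_exam[idx]] = hi_sbp[idx]

    smoke = np.zeros((n, 4), dtype=int)
    smoke_wave = rng.integers(0, 4, size=n)
    idx = np.nonzero(smoker)[0]
    smoke[idx, smoke_wave[idx]] = 1
    # smokers may report in further waves too
    extra = rng.uniform(size=(n, 4)) < 0.5
    smoke[smoker] |= extra[smoker]

    sex = np.where(rng.uniform(size=n) < 0.5, "female", "male")
    source = np.array(["imputed"] * n, dtype=object)
    source[rng.permutation(n)[:cfg.n_ngs]] = "ngs"

    df = pd.DataFrame({"id": samples, "sex": sex})
    for k in range(4):
        df[f"sbp{k + 1}"] = sbp[:, k]
        df[f"dbp{k + 1}"] = dbp[:, k]
        df[f"smoke{k + 1}"] = smoke[:, k]
    df["sequence_source"] = source
    return PhenotypeTable(df)


@dataclass
class SimulatedDataset:
    """Bundle of truth, both platforms' calls, and phenotypes."""

    truth: GenotypeMatrix
    seq: GenotypeMatrix
    micro: GenotypeMatrix
    phenotypes: PhenotypeTable
    config: SimulationConfig

    def pair(self) -> HarmonizedPair:
        """Harmonize the two simulated call sets (no exclusions expected)."""
        return harmonize(self.seq, self.micro)


def null_welch_pvalues(n_reps: int, base_seed: int = 0, n_snps: int = 40,
                       n_samples: int = 80, cell: tuple[int, int] = (0, 0),
                       error_matrix: Optional[np.ndarray] = None
                       ) -> np.ndarray:
    """Null-calibration p-values for the phenotype-group Welch test.

    Each replicate simulates a nondifferential study (same error process
    in both phenotype groups, so the no-difference null holds exactly),
    runs the hypertensive-vs-nonhypertensive comparison, and records the
    p-value of one conditional-rate cell.  Under the null these p-values
    should be approximately uniform, so the fraction below alpha
    estimates the test's actual size.  Replicate seeds are
    ``base_seed * 1009 + rep`` reduced mod 2^31 - 1.
    """
    from gtconcord.differential import compare_groups

    err = (np.asarray(error_matrix) if error_matrix is not None
           else np.array([[0.92, 0.05, 0.03],
                          [0.05, 0.90, 0.05],
                          [0.03, 0.05, 0.92]]))
    out = []
    for rep in range(n_reps):
        seed = (base_seed * 1009 + rep) % (2**31 - 1)
        cfg = SimulationConfig(
            n_snps=n_snps, n_samples=n_samples, seed=seed,
            maf_spec=(0.2, 0.5),
            seq=PlatformConfig(err, missing_rate=0.0),
            micro=PlatformConfig(np.eye(3), missing_rate=0.0),
            phenotype_prevalence=0.5)
        ds = simulate_paired_dataset(cfg)
        comp = compare_groups(ds.pair(), ds.phenotypes, "hypertension")
        out.append(comp.p[cell])
    return np.asarray(out)


def simulate_paired_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: truth, two platforms, phenotypes."""
    phen = simulate_phenotypes(cfg)
    labels = (phen.data["hypertensive"] == "yes").to_numpy().astype(int)
    truth = simulate_truth(cfg)
    mafs = cfg.mafs()
    seq = simulate_platform_calls(truth, cfg.seq, STREAM_SEQ, cfg,
                                  phenotype=labels, mafs=mafs)
    micro = simulate_platform_calls(truth, cfg.micro, STREAM_MICRO, cfg,
                                    phenotype=labels, mafs=mafs)
    return SimulatedDataset(truth, seq, micro, phen, cfg)
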