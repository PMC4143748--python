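"""Cross-classification and conditional concordance statistics.

The central object is the 4x4 cross-classification of call pairs over
{AA, AB, BB, XX}: rows index the sequence-platform call, columns the
microarray call, so cell (i, j) counts (variant, sample) pairs where the
sequence platform called *i* and the microarray called *j*.  From the
pooled table come the headline discordance proportions; from per-SNP
tables come conditional concordance rates P(seq = i | micro = j), their
across-SNP summaries, and MAF-stratified versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gtconcord.calls import AA, AB, BB, XX, CALL_LABELS
from gtconcord.genio import HarmonizedPair

_CALLED = slice(0, 3)  # AA, AB, BB


@dataclass
class CrossClassTable:
    """4x4 pooled counts of (sequence, microarray) call pairs.

    ``counts[i, j]`` = number of pairs with sequence call i and
    microarray call j, category order (AA, AB, BB, XX).
    """

    counts: np.ndarray
    n_snps: int
    n_samples: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_discordant_called(self) -> int:
        """Pairs where both platforms called and the calls differ."""
        called = self.counts[_CALLED, _CALLED]
        return int(called.sum() - np.trace(called))

    @property
    def n_missing_either(self) -> int:
        """Pairs missing on at least one platform (XX-XX included once)."""
        return int(self.counts[XX, :].sum() + self.counts[:, XX].sum()
                   - self.counts[XX, XX])

    @property
    def n_missing_one(self) -> int:
        """Pairs where exactly one platform is missing."""
        return self.n_missing_either - int(self.counts[XX, XX])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=CALL_LABELS, columns=CALL_LABELS)
        df.index.name = "sequence"
        df.columns.name = "microarray"
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame().copy()
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        df.to_csv(path, sep="\t")

    def __add__(self, other: "CrossClassTable") -> "CrossClassTable":
        return CrossClassTable(self.counts + other.counts,
                               self.n_snps, self.n_samples + other.n_samples)


def cross_classify(pair: HarmonizedPair, sample_subset=None,
                   snp_subset=None) -> CrossClassTable:
    """Pool the 16-cell cross-classification over SNPs and samples.

    Every (variant, sample) pair increments exactly one cell, so the
    grand total equals n_snps x n_samples.
    """
    sub = _subset_pair(pair, sample_subset, snp_subset)
    if sub.n_variants == 0 or sub.n_samples == 0:
        raise ValueError("empty SNP or sample subset")
    joint = 4 * sub.seq.calls.astype(np.int64) + sub.micro.calls
    counts = np.bincount(joint.ravel(), minlength=16).reshape(4, 4)
    return CrossClassTable(counts, sub.n_variants, sub.n_samples)


def overall_discordance(t: CrossClassTable,
                        mode: str = "including_missing") -> float:
    """Overall proportion of discordant pairs.

    ``called_only``: the six off-diagonal cells among called genotypes
    over the grand total.  ``including_missing`` adds pairs where exactly
    one platform is missing; XX-XX pairs count as concordant-missing.
    Both proportions use the grand total (all 16 cells) as denominator.
    """
    if t.total == 0:
        raise ValueError("empty cross-classification table")
    disc = t.n_discordant_called
    if mode == "including_missing":
        disc += t.n_missing_one
    elif mode != "called_only":
        raise ValueError(f"unknown mode {mode!r}")
    return disc / t.total


@dataclass
class ConditionalRateSet:
    """Per-SNP conditional rates P(sequence call = i | microarray call = j).

    ``rates[s, i, j]`` is the conditional proportion for SNP s; columns
    with a zero denominator are flagged invalid (``valid[s, j]`` False)
    and carry NaN rates.
    """

    rs_ids: list[str]
    counts: np.ndarray   # (n_snps, 4, 4) int64
    rates: np.ndarray    # (n_snps, 4, 4) float, NaN where invalid
    col_totals: np.ndarray  # (n_snps, 4)
    valid: np.ndarray    # (n_snps, 4) bool

    @property
    def n_snps(self) -> int:
        return len(self.rs_ids)

    def cell_rates(self, i: int, j: int) -> np.ndarray:
        """Across-SNP vector of P(seq=i | micro=j), NaN where invalid."""
        return self.rates[:, i, j]


def per_snp_conditional_rates(pair: HarmonizedPair,
                              sample_subset=None) -> ConditionalRateSet:
    """Column-normalised per-SNP 4x4 tables, conditioned on the microarray."""
    sub = _subset_pair(pair, sample_subset, None)
    if sub.n_variants == 0 or sub.n_samples == 0:
        raise ValueError("empty pair")
    joint = 4 * sub.seq.calls.astype(np.int64) + sub.micro.calls
    snp_idx = np.repeat(np.arange(sub.n_variants), sub.n_samples)
    flat = snp_idx * 16 + joint.ravel()
    counts = np.bincount(flat, minlength=sub.n_variants * 16)
    counts = counts.reshape(sub.n_variants, 4, 4)
    col_totals = counts.sum(axis=1)
    valid = col_totals > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / col_totals[:, None, :]
    rates[~np.repeat(valid[:, None, :], 4, axis=1)] = np.nan
    return ConditionalRateSet(sub.rs_ids, counts, rates, col_totals, valid)


@dataclass
class RateSummary:
    """Across-SNP summary of the per-SNP conditional rates.

    Each 4x4 cell is averaged over the SNPs whose conditioning column has
    a positive denominator (unweighted: each SNP counts once).  Both the
    across-SNP standard deviation and the standard error of the mean are
    reported; cells with no valid SNP are NaN with n = 0.
    """

    mean: np.ndarray  # (4, 4)
    sd: np.ndarray
    se: np.ndarray
    n: np.ndarray     # (4, 4) int, SNPs contributing to each cell

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, seq_lab in enumerate(CALL_LABELS):
            for j, micro_lab in enumerate(CALL_LABELS):
                rows.append({"seq_call": seq_lab, "micro_call": micro_lab,
                             "mean": self.mean[i, j], "sd": self.sd[i, j],
                             "se": self.se[i, j], "n_snps": self.n[i, j]})
        return pd.DataFrame(rows)


def summarize_rates(rates: ConditionalRateSet, snp_subset=None,
                    weighted: bool = False) -> RateSummary:
    """Average the per-SNP conditional rates across SNPs.

    ``weighted=True`` pools counts across SNPs instead (each pair counts
    once), the count-weighted alternative to the default equal-weight
    per-SNP mean.
    """
    if snp_subset is not None:
        idx = {rs: k for k, rs in enumerate(rates.rs_ids)}
        sel = np.array([idx[rs] for rs in snp_subset])
        rates = ConditionalRateSet(
            [rates.rs_ids[k] for k in sel], rates.counts[sel],
            rates.rates[sel], rates.col_totals[sel], rates.valid[sel])
    n = rates.valid.sum(axis=0).astype(np.int64)     # per column j
    n_cell = np.repeat(n[None, :], 4, axis=0)
    if weighted:
        pooled = rates.counts.sum(axis=0)
        tot = pooled.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = pooled / tot[None, :]
        sd = np.full((4, 4), np.nan)
        se = np.full((4, 4), np.nan)
        return RateSummary(mean, sd, se, n_cell)
    mean, sd = _nan_mean_sd(rates.rates)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = sd / np.sqrt(np.where(n_cell > 0, n_cell, np.nan))
    return RateSummary(mean, sd, se, n_cell)


def _nan_mean_sd(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample (ddof=1) SD over axis 0, ignoring NaN.

    Warning-free replacement for nanmean/nanstd on all-NaN slices: mean
    is NaN for empty cells, SD is NaN below 2 observations.
    """
    mask = ~np.isnan(a)
    cnt = mask.sum(axis=0)
    filled = np.where(mask, a, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=0) / cnt
        ss = np.where(mask, (a - mean[None]) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(ss / (cnt - 1))
    mean = np.where(cnt > 0, mean, np.nan)
    sd = np.where(cnt > 1, sd, np.nan)
    return mean, sd


# ---------------------------------------------------------------------
# MAF computation and stratification
# ---------------------------------------------------------------------

def snp_maf(gm) -> np.ndarray:
    """Per-variant minor-allele frequency from called genotypes.

    MAF = (het + 2 x minor-homozygote) / (2 x called); NaN when every
    call is missing.  Note this is the frequency of the *labelled* minor
    allele, which can exceed 0.5 in a sample.
    """
    calls = gm.calls
    called = (calls != XX).sum(axis=1)
    minor = (calls == AB).sum(axis=1) + 2 * (calls == BB).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = minor / (2.0 * called)
    maf[called == 0] = np.nan
    return maf


DEFAULT_MAF_BINS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def maf_stratified_rates(pair: HarmonizedPair,
                         bins=DEFAULT_MAF_BINS,
                         maf_source: str = "microarray"):
    """Per-MAF-bin rate summaries and overall discordance.

    SNPs are assigned to half-open bins [lo, hi) built from ``bins``
    (the last bin is closed on the right); MAF below the first edge goes
    to the first bin, ties at 0.5 to the last.  SNPs whose source calls
    are all missing are left unbinned and reported as such.

    Returns a DataFrame with one row per bin: edges, n_snps, overall
    discordance in both modes, and the mean diagonal (concordant-called)
    conditional rates.
    """
    if maf_source not in ("microarray", "sequence"):
        raise ValueError(f"unknown maf_source {maf_source!r}")
    src = pair.micro if maf_source == "microarray" else pair.seq
    maf = snp_maf(src)
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bins must be increasing edges with >= 2 entries")
    rs = np.asarray(pair.rs_ids, dtype=object)
    unbinned = np.isnan(maf)
    # clip: everything below the first edge falls in the first bin,
    # maf == last edge in the last bin
    bin_idx = np.digitize(maf, edges[1:-1], right=False)
    rows = []
    rateset = per_snp_conditional_rates(pair)
    for b in range(len(edges) - 1):
        in_bin = (~unbinned) & (bin_idx == b)
        row = {"maf_lo": edges[b], "maf_hi": edges[b + 1],
               "n_snps": int(in_bin.sum())}
        if in_bin.any():
            sub_rs = list(rs[in_bin])
            tab = cross_classify(pair, snp_subset=sub_rs)
            summ = summarize_rates(rateset, snp_subset=sub_rs)
            row["discordance_including_missing"] = overall_discordance(
                tab, "including_missing")
            row["discordance_called_only"] = overall_discordance(
                tab, "called_only")
            for k, lab in zip((AA, AB, BB), ("AA", "AB", "BB")):
                row[f"mean_P_{lab}_given_{lab}"] = summ.mean[k, k]
        else:
            row.update(discordance_including_missing=np.nan,
                       discordance_called_only=np.nan,
                       mean_P_AA_given_AA=np.nan, mean_P_AB_given_AB=np.nan,
                       mean_P_BB_given_BB=np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_unbinned"] = int(unbinned.sum())
    out.attrs["unbinned_rs_ids"] = list(rs[unbinned])
    return out


def _subset_pair(pair: HarmonizedPair, sample_subset, snp_subset):
    if sample_subset is None and snp_subset is None:
        return pair
    if sample_subset is not None:
        missing = set(sample_subset) - set(pair.samples)
        if missing:
            raise ValueError(f"samples not in pair: {sorted(missing)[:5]}")
    if snp_subset is not None:
        missing = set(snp_subset) - set(pair.rs_ids)
        if missing:
            raise ValueError(f"rs_ids not in pair: {sorted(missing)[:5]}")
    return pair.subset(rs_ids=snp_subset, samples=sample_subset)
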