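"""Phenotype strata and differential-concordance tests.

Concordance differing systematically between phenotype groups
(differential genotyping error) inflates type I error in downstream
association tests, whereas phenotype-independent (nondifferential) error
only costs power — which is why the per-group comparison matters for QC.

Strata are derived from raw exam records: hypertension from up to four
exams of systolic/diastolic blood pressure (systolic > 140 mm Hg or
diastolic > 90 mm Hg at any exam, strict inequalities), smoking from up
to four self-report waves (any wave positive), plus sex and the sample's
sequence source (directly sequenced vs imputed).  Per-SNP conditional
rates are computed within each stratum's samples and compared cell by
cell with two-sample Welch t-tests across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gtconcord.calls import CALL_LABELS
from gtconcord.concordance import (
    ConditionalRateSet, RateSummary, per_snp_conditional_rates,
    summarize_rates,
)
from gtconcord.genio import HarmonizedPair

#: below this, p-values are printed as an inequality (double-precision
#: resolution near 1); the numeric value is kept alongside
P_FLOOR = 2.220446049250313e-16

STRATIFIERS = ("hypertension", "smoking", "sex", "sequence_source")

PHENOTYPE_COLUMNS = (
    ["id", "sex"]
    + [f"sbp{i}" for i in range(1, 5)] + [f"dbp{i}" for i in range(1, 5)]
    + [f"smoke{i}" for i in range(1, 5)] + ["sequence_source"]
)


def derive_hypertension(sbp, dbp) -> str:
    """Classify a sample from up to four exams of blood pressure.

    'yes' if any present exam has systolic > 140 mm Hg or diastolic >
    90 mm Hg (strict: 140/90 exactly is not hypertensive); 'no' if every
    present exam fails both; 'unknown' with no usable exam.  Missing
    entries are None/NaN.
    """
    sbp, dbp = list(sbp), list(dbp)
    if len(sbp) != len(dbp):
        raise ValueError("sbp and dbp must have equal length")
    if len(sbp) > 4:
        raise ValueError("at most 4 exams supported")
    any_present = False
    for s, d in zip(sbp, dbp):
        s_ok, d_ok = _present(s), _present(d)
        if s_ok and s <= 0 or d_ok and d <= 0:
            raise ValueError("blood pressures must be positive")
        if s_ok or d_ok:
            any_present = True
        if (s_ok and s > 140) or (d_ok and d > 90):
            return "yes"
    return "no" if any_present else "unknown"


def derive_smoking(smoke) -> str:
    """'yes' if any of up to four waves self-reports smoking (1)."""
    smoke = list(smoke)
    if len(smoke) > 4:
        raise ValueError("at most 4 waves supported")
    any_present = False
    for v in smoke:
        if not _present(v):
            continue
        if v not in (0, 1):
            raise ValueError(f"smoking indicator must be 0/1, got {v!r}")
        any_present = True
        if v == 1:
            return "yes"
    return "no" if any_present else "unknown"


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v))


class PhenotypeTable:
    """Per-sample phenotype strata derived from raw exam records.

    Wraps a DataFrame indexed by sample id with the raw fields (sex,
    sbp1..4, dbp1..4, smoke1..4, sequence_source) and the derived binary
    labels ``hypertensive`` and ``smoker``; derivations are recomputed
    from the raw fields at construction so they can never go stale.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if "id" in df.columns:
            df = df.set_index("id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        for col in PHENOTYPE_COLUMNS[1:]:
            if col not in df.columns:
                df[col] = np.nan
        sbp = df[[f"sbp{i}" for i in range(1, 5)]].to_numpy(dtype=float)
        dbp = df[[f"dbp{i}" for i in range(1, 5)]].to_numpy(dtype=float)
        smoke = df[[f"smoke{i}" for i in range(1, 5)]].to_numpy(dtype=float)
        df["hypertensive"] = [derive_hypertension(s, d)
                              for s, d in zip(sbp, dbp)]
        df["smoker"] = [derive_smoking(s[~np.isnan(s)]) for s in smoke]
        df["sex"] = df["sex"].fillna("unknown").replace("", "unknown")
        df["sequence_source"] = (df["sequence_source"]
                                 .fillna("unknown").replace("", "unknown"))
        bad = set(df["sequence_source"]) - {"ngs", "imputed", "unknown"}
        if bad:
            raise ValueError(f"invalid sequence_source values: {sorted(bad)}")
        self.data = df

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str,
                                                "sequence_source": str})
        missing = {"id"} - set(df.columns)
        if missing:
            raise ValueError(f"phenotype TSV lacks column(s) {missing}")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.reset_index(names="id").to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def strata(self, stratifier: str) -> pd.Series:
        """Per-sample group label for a stratifier; 'unknown' = excluded."""
        if stratifier == "hypertension":
            return self.data["hypertensive"]
        if stratifier == "smoking":
            return self.data["smoker"]
        if stratifier in ("sex", "sequence_source"):
            return self.data[stratifier]
        raise ValueError(
            f"unknown stratifier {stratifier!r}; expected one of {STRATIFIERS}")

    def group_samples(self, stratifier: str) -> dict[str, list[str]]:
        lab = self.strata(stratifier)
        groups = {}
        for g in sorted(set(lab) - {"unknown"}):
            groups[g] = list(lab.index[lab == g])
        return groups


def _two_groups(pair: HarmonizedPair, phen: PhenotypeTable,
                stratifier: str) -> dict[str, list[str]]:
    groups = phen.group_samples(stratifier)
    in_pair = set(pair.samples)
    groups = {g: [s for s in ss if s in in_pair] for g, ss in groups.items()}
    groups = {g: ss for g, ss in groups.items() if ss}
    if len(groups) != 2:
        raise ValueError(
            f"stratifier {stratifier!r} must yield exactly 2 non-empty "
            f"strata among the pair's samples; got "
            f"{ {g: len(s) for g, s in groups.items()} }")
    return groups


def group_rate_summaries(pair: HarmonizedPair, phen: PhenotypeTable,
                         stratifier: str) -> dict[str, RateSummary]:
    """Across-SNP conditional-rate summaries within each stratum."""
    groups = _two_groups(pair, phen, stratifier)
    return {g: summarize_rates(per_snp_conditional_rates(pair, samples))
            for g, samples in groups.items()}


@dataclass
class GroupComparison:
    """Per-cell Welch t-tests of per-SNP conditional rates between groups."""

    group_a: str
    group_b: str
    mean_a: np.ndarray
    mean_b: np.ndarray
    sd_a: np.ndarray
    sd_b: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    paired: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, seq_lab in enumerate(CALL_LABELS):
            for j, micro_lab in enumerate(CALL_LABELS):
                rows.append({
                    "seq_call": seq_lab, "micro_call": micro_lab,
                    f"mean_{self.group_a}": self.mean_a[i, j],
                    f"mean_{self.group_b}": self.mean_b[i, j],
                    f"sd_{self.group_a}": self.sd_a[i, j],
                    f"sd_{self.group_b}": self.sd_b[i, j],
                    f"n_{self.group_a}": self.n_a[i, j],
                    f"n_{self.group_b}": self.n_b[i, j],
                    "t": self.t[i, j], "df": self.df[i, j],
                    "p": self.p[i, j],
                    "p_str": format_p(self.p[i, j]),
                    "p_bonferroni": min(self.p[i, j] * 16, 1.0)
                    if np.isfinite(self.p[i, j]) else np.nan,
                })
        return pd.DataFrame(rows)


def format_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.6g}"


def compare_groups(pair: HarmonizedPair, phen: PhenotypeTable,
                   stratifier: str, paired: bool = False) -> GroupComparison:
    """Cell-by-cell t-tests of per-SNP conditional rates between two strata.

    For each of the 16 (sequence, microarray) cells, the per-SNP rates of
    group A and group B are compared with an unpaired two-sample Welch
    (unequal-variance) t-test over SNPs.  SNPs lacking a valid
    conditioning denominator in either group are dropped from that cell's
    test (complete case per cell).  ``paired=True`` instead runs a paired
    t-test on the per-SNP rate differences — the natural choice when both
    "groups" observe the same SNPs, as in a technology comparison.

    Cells where either group has fewer than 2 usable SNPs, or where the
    rate vectors are constant, get NaN statistics.
    """
    groups = _two_groups(pair, phen, stratifier)
    (ga, sa), (gb, sb) = groups.items()
    ra = per_snp_conditional_rates(pair, sa)
    rb = per_snp_conditional_rates(pair, sb)
    return _compare_ratesets(ra, rb, ga, gb, paired)


def _compare_ratesets(ra: ConditionalRateSet, rb: ConditionalRateSet,
                      name_a: str, name_b: str,
                      paired: bool = False) -> GroupComparison:
    shape = (4, 4)
    mean_a = np.full(shape, np.nan); mean_b = np.full(shape, np.nan)
    sd_a = np.full(shape, np.nan); sd_b = np.full(shape, np.nan)
    n_a = np.zeros(shape, dtype=np.int64); n_b = np.zeros(shape, dtype=np.int64)
    t = np.full(shape, np.nan); df = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    for i in range(4):
        for j in range(4):
            xa, xb = ra.rates[:, i, j], rb.rates[:, i, j]
            if paired:
                ok = ~np.isnan(xa) & ~np.isnan(xb)
                xa, xb = xa[ok], xb[ok]
            else:
                both = ~np.isnan(xa) & ~np.isnan(xb)
                xa, xb = xa[both], xb[both]
            n_a[i, j], n_b[i, j] = len(xa), len(xb)
            if len(xa):
                mean_a[i, j], sd_a[i, j] = xa.mean(), xa.std(ddof=1) if len(xa) > 1 else np.nan
            if len(xb):
                mean_b[i, j], sd_b[i, j] = xb.mean(), xb.std(ddof=1) if len(xb) > 1 else np.nan
            if len(xa) < 2 or len(xb) < 2:
                continue
            if paired:
                d = xa - xb
                if np.allclose(d.std(ddof=1), 0):
                    if np.allclose(d, 0):
                        t[i, j], p[i, j], df[i, j] = 0.0, 1.0, len(d) - 1
                    continue
                res = stats.ttest_rel(xa, xb)
                t[i, j], p[i, j] = res.statistic, res.pvalue
                df[i, j] = len(d) - 1
            else:
                if np.allclose(xa.std(ddof=1), 0) and np.allclose(xb.std(ddof=1), 0):
                    if np.isclose(xa.mean(), xb.mean()):
                        t[i, j], p[i, j] = 0.0, 1.0
                        df[i, j] = len(xa) + len(xb) - 2
                    continue
                res = stats.ttest_ind(xa, xb, equal_var=False)
                t[i, j], p[i, j] = res.statistic, res.pvalue
                df[i, j] = res.df
    p = np.where(np.isfinite(p), np.maximum(p, np.finfo(float).tiny), p)
    return GroupComparison(name_a, name_b, mean_a, mean_b, sd_a, sd_b,
                           n_a, n_b, t, df, p, paired=paired)


def compare_technologies(rates_a: ConditionalRateSet,
                         rates_b: ConditionalRateSet,
                         name_a: str = "ngs", name_b: str = "imputed",
                         paired: bool = False) -> GroupComparison:
    """Welch t-tests between two rate sets over the same SNPs.

    Used for the technology comparison (e.g. directly sequenced vs
    imputed samples): the rate sets come from the same pair restricted to
    each technology's samples, so each SNP contributes one rate per side.
    """
    if rates_a.rs_ids != rates_b.rs_ids:
        raise ValueError("rate sets must cover the same SNPs in order")
    return _compare_ratesets(rates_a, rates_b, name_a, name_b, paired)
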