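"""Model/Results front-end tying the pipeline stages together.

``GenotypeConcordance`` is constructed from data (a harmonized pair of
call sets, or the raw files via :meth:`GenotypeConcordance.from_files`)
plus options; ``fit()`` runs the full concordance evaluation and returns
a ``ConcordanceResults`` carrying the pooled cross-classification, the
overall discordance proportions, across-SNP conditional-rate summaries,
MAF-stratified rates, per-stratifier group comparisons, the resolved
dosage matrix, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from gtconcord.calls import AA, AB, BB, CALL_LABELS
from gtconcord.concordance import (
    DEFAULT_MAF_BINS, ConditionalRateSet, CrossClassTable, RateSummary,
    cross_classify, maf_stratified_rates, overall_discordance,
    per_snp_conditional_rates, summarize_rates,
)
from gtconcord.differential import (
    GroupComparison, PhenotypeTable, compare_groups, format_p,
    group_rate_summaries,
)
from gtconcord.dosage import DosageMatrix, build_dosage_matrix
from gtconcord.genio import GenotypeMatrix, HarmonizedPair, harmonize, read_genotypes


class GenotypeConcordance:
    """Cross-platform genotype concordance model.

    Parameters
    ----------
    pair : HarmonizedPair
        Sample- and variant-aligned call sets (sequence platform vs
        microarray) with consistent alleles.
    phenotypes : PhenotypeTable, optional
        Required for any phenotype or technology stratification.
    stratifiers : sequence of str
        Which group comparisons ``fit`` should run; subset of
        {'hypertension', 'smoking', 'sex', 'sequence_source'}.
    maf_bins : sequence of float
        MAF bin edges for the stratified rates.
    maf_source : {'microarray', 'sequence'}
        Which platform's called genotypes define each SNP's MAF.
    """

    def __init__(self, pair: HarmonizedPair,
                 phenotypes: Optional[PhenotypeTable] = None,
                 stratifiers=(), maf_bins=DEFAULT_MAF_BINS,
                 maf_source: str = "microarray"):
        self.pair = pair
        self.phenotypes = phenotypes
        self.stratifiers = tuple(stratifiers)
        self.maf_bins = tuple(maf_bins)
        self.maf_source = maf_source
        if self.stratifiers and phenotypes is None:
            raise ValueError("stratifiers requested but no phenotype table")

    @classmethod
    def from_matrices(cls, seq: GenotypeMatrix, micro: GenotypeMatrix,
                      phenotypes: Optional[PhenotypeTable] = None,
                      allow_strand_flip: bool = False, **kwargs
                      ) -> "GenotypeConcordance":
        pair = harmonize(seq, micro, allow_strand_flip=allow_strand_flip)
        return cls(pair, phenotypes, **kwargs)

    @classmethod
    def from_files(cls, seq_path, seq_format, micro_path, micro_format,
                   phenotype_path=None, allow_strand_flip: bool = False,
                   **kwargs) -> "GenotypeConcordance":
        seq = read_genotypes(seq_path, seq_format)
        micro = read_genotypes(micro_path, micro_format)
        phen = (PhenotypeTable.from_tsv(phenotype_path)
                if phenotype_path is not None else None)
        return cls.from_matrices(seq, micro, phen,
                                 allow_strand_flip=allow_strand_flip, **kwargs)

    def fit(self, weighted: bool = False,
            paired_technology: bool = False) -> "ConcordanceResults":
        """Run the full evaluation.

        ``weighted`` switches the across-SNP summary to count-weighted
        pooling; ``paired_technology`` makes the sequence_source
        comparison a paired-per-SNP t-test instead of Welch.
        """
        pair = self.pair
        table = cross_classify(pair)
        rates = per_snp_conditional_rates(pair)
        summary = summarize_rates(rates, weighted=weighted)
        maf_table = maf_stratified_rates(pair, self.maf_bins, self.maf_source)
        comparisons: dict[str, GroupComparison] = {}
        summaries: dict[str, dict[str, RateSummary]] = {}
        for strat in self.stratifiers:
            paired = paired_technology and strat == "sequence_source"
            comparisons[strat] = compare_groups(pair, self.phenotypes, strat,
                                                paired=paired)
            summaries[strat] = group_rate_summaries(pair, self.phenotypes,
                                                    strat)
        dosages = build_dosage_matrix(pair)
        return ConcordanceResults(
            model=self, crossclass=table, conditional_rates=rates,
            rate_summary=summary, maf_table=maf_table,
            group_comparisons=comparisons, group_summaries=summaries,
            dosages=dosages)


@dataclass
class ConcordanceResults:
    """Fitted concordance evaluation (returned by ``GenotypeConcordance.fit``)."""

    model: GenotypeConcordance
    crossclass: CrossClassTable
    conditional_rates: ConditionalRateSet
    rate_summary: RateSummary
    maf_table: pd.DataFrame
    group_comparisons: dict[str, GroupComparison]
    group_summaries: dict[str, dict[str, RateSummary]]
    dosages: DosageMatrix

    @property
    def discordance_including_missing(self) -> float:
        return overall_discordance(self.crossclass, "including_missing")

    @property
    def discordance_called_only(self) -> float:
        return overall_discordance(self.crossclass, "called_only")

    def summary(self) -> str:
        """Human-readable report of the headline statistics."""
        t = self.crossclass
        pair = self.model.pair
        lines = [
            "Genotype concordance evaluation",
            "=" * 64,
            f"SNPs analysed:            {t.n_snps:>12,}",
            f"Samples:                  {t.n_samples:>12,}",
            f"Call pairs:               {t.total:>12,}",
            f"Matched SNPs:             {pair.n_matched:>12,}"
            f"   (excluded {len(pair.exclusions):,})",
            "",
            "Cross-classification (rows seq, cols micro):",
        ]
        df = t.to_frame()
        lines.append(df.to_string())
        lines += [
            "",
            f"Discordant called pairs:  {t.n_discordant_called:>12,}",
            f"Missing on >=1 platform:  {t.n_missing_either:>12,}",
            "Overall discordance (incl. missing): "
            f"{100 * self.discordance_including_missing:.2f}%",
            "Discordant called genotypes:         "
            f"{100 * self.discordance_called_only:.2f}%",
            "",
            "Mean per-SNP conditional concordance (diagonal cells):",
        ]
        for k, lab in zip((AA, AB, BB), ("AA", "AB", "BB")):
            m, sd, n = (self.rate_summary.mean[k, k],
                        self.rate_summary.sd[k, k], self.rate_summary.n[k, k])
            sd_txt = f"{sd:.3f}" if np.isfinite(sd) else "NA"
            lines.append(f"  P(seq {lab} | micro {lab}) = {m:.4f} "
                         f"(sd {sd_txt}, n={n})")
        for strat, comp in self.group_comparisons.items():
            lines += ["", f"Group comparison [{strat}]: "
                          f"{comp.group_a} vs {comp.group_b}"
                          f"{' (paired)' if comp.paired else ''}"]
            for i in (AA, AB, BB):
                j = i
                lines.append(
                    f"  P(seq {CALL_LABELS[i]} | micro {CALL_LABELS[j]}): "
                    f"{comp.mean_a[i, j]:.4f} vs {comp.mean_b[i, j]:.4f}, "
                    f"t={comp.t[i, j]:.2f}, p={format_p(comp.p[i, j])}")
        prov = self.dosages.provenance_counts()
        lines += ["", "Dosage resolution: "
                  + ", ".join(f"{k}={v:,}" for k, v in prov.items())]
        return "\n".join(lines)

    def save_tables(self, outdir) -> dict[str, Path]:
        """Write the report bundle; returns {artifact name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        p = outdir / "table1_counts.tsv"
        self.crossclass.to_tsv(p)
        paths["crossclass"] = p

        p = outdir / "table2_conditional_rates.tsv"
        frames = [self.rate_summary.to_frame().assign(group="all")]
        for strat, summ in self.group_summaries.items():
            for g, rs in summ.items():
                frames.append(rs.to_frame().assign(group=f"{strat}:{g}"))
        pd.concat(frames, ignore_index=True).to_csv(
            p, sep="\t", index=False, float_format="%.6g")
        paths["conditional_rates"] = p

        for strat, comp in self.group_comparisons.items():
            p = outdir / f"table3_group_comparison_{strat}.tsv"
            comp.to_frame().to_csv(p, sep="\t", index=False,
                                   float_format="%.6g")
            paths[f"comparison_{strat}"] = p

        p = outdir / "maf_strata.tsv"
        self.maf_table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths["maf_strata"] = p

        p = outdir / "exclusions.tsv"
        self.model.pair.write_exclusions(p)
        paths["exclusions"] = p

        p = outdir / "dosages.tsv"
        self.dosages.to_tsv(p, variants=self.model.pair.seq.variants)
        paths["dosages"] = p

        p = outdir / "run_log.txt"
        pair = self.model.pair
        with open(p, "w") as fh:
            fh.write(f"matched\t{pair.n_matched}\n"
                     f"retained\t{pair.n_variants}\n"
                     f"excluded\t{len(pair.exclusions)}\n"
                     f"samples\t{pair.n_samples}\n"
                     f"call_pairs\t{self.crossclass.total}\n")
        paths["run_log"] = p
        return paths
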