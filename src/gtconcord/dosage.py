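"""Resolving discordant call pairs into minor-allele dosages.

When two platforms disagree and neither is a gold standard, a 50-50
weighting of the two calls is a reasonable default for downstream
association analysis: the resolved genotype is the mean of the two
calls' minor-allele dosages, so a major-homozygote/heterozygote pair
becomes 0.5 and a heterozygote/minor-homozygote pair 1.5.  Pairs with
one missing call use the available call; pairs missing on both sides
stay missing.  The rule is symmetric in the two platforms and every
resolved value lies in {0, 0.5, 1, 1.5, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gtconcord.calls import CALL_LABELS, DOSAGE_OF_CALL, XX
from gtconcord.genio import HarmonizedPair

PROVENANCE_LABELS = ("concordant", "one_missing", "resolved_discordant",
                     "both_missing")
CONCORDANT, ONE_MISSING, RESOLVED_DISCORDANT, BOTH_MISSING = range(4)


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    dose = np.full((4, 4), np.nan)
    prov = np.empty((4, 4), dtype=np.int8)
    for a in range(4):
        for b in range(4):
            if a == XX and b == XX:
                prov[a, b] = BOTH_MISSING
            elif a == XX or b == XX:
                prov[a, b] = ONE_MISSING
                dose[a, b] = DOSAGE_OF_CALL[b if a == XX else a]
            elif a == b:
                prov[a, b] = CONCORDANT
                dose[a, b] = DOSAGE_OF_CALL[a]
            else:
                prov[a, b] = RESOLVED_DISCORDANT
                dose[a, b] = (DOSAGE_OF_CALL[a] + DOSAGE_OF_CALL[b]) / 2.0
    return dose, prov


_DOSE_TABLE, _PROV_TABLE = _build_tables()


def resolve_pair(g_seq: int, g_micro: int) -> tuple[float, str]:
    """Resolve one call pair to (dosage, provenance).

    Calls are codes 0=AA, 1=AB, 2=BB, 3=XX; dosages count minor alleles
    (AA=0, AB=1, BB=2).  Concordant pairs keep their dosage; one-missing
    pairs take the called side's dosage; discordant called pairs take the
    mean of the two dosages (0.5 for AA/AB, 1.5 for AB/BB, 1.0 for the
    opposite-homozygote AA/BB case); double-missing pairs return NaN.
    """
    if not (0 <= g_seq <= 3 and 0 <= g_micro <= 3):
        raise ValueError("calls must be codes in 0..3")
    return (float(_DOSE_TABLE[g_seq, g_micro]),
            PROVENANCE_LABELS[_PROV_TABLE[g_seq, g_micro]])


@dataclass
class DosageMatrix:
    """Variants x samples minor-allele dosages with per-cell provenance."""

    rs_ids: list[str]
    samples: list[str]
    dosages: np.ndarray      # float, NaN where both platforms missing
    provenance: np.ndarray   # int8 codes into PROVENANCE_LABELS

    def provenance_counts(self) -> dict[str, int]:
        flat = np.bincount(self.provenance.ravel(), minlength=4)
        return dict(zip(PROVENANCE_LABELS, flat.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.rs_ids,
                            columns=self.samples)

    def to_tsv(self, path, variants: pd.DataFrame | None = None) -> None:
        """Dosage TSV in the genotype-TSV layout (numeric cells, NA=missing)."""
        body = self.to_frame().reset_index(names="rs_id")
        if variants is not None:
            body = variants.merge(body, on="rs_id")
        body.to_csv(path, sep="\t", index=False, na_rep="NA",
                    float_format="%g")


    def to_vcf(self, path, variants: pd.DataFrame) -> None:
        """Minimal VCF 4.2 with the dosage in the DS FORMAT field.

        ``variants`` supplies chrom/pos/alleles (the harmonized pair's
        variant table); REF is the major and ALT the minor allele, so DS
        counts ALT copies.  Missing dosages are written as ``.``.
        """
        meta = variants.set_index("rs_id")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Minor-allele dosage, 50-50 resolved">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for k, rs in enumerate(self.rs_ids):
                row = meta.loc[rs]
                cells = "\t".join(
                    "." if np.isnan(d) else f"{d:g}"
                    for d in self.dosages[k])
                fh.write(f"{row.chrom}\t{row.pos}\t{rs}\t{row.allele_major}\t"
                         f"{row.allele_minor}\t.\t.\t.\tDS\t{cells}\n")


def build_dosage_matrix(pair: HarmonizedPair) -> DosageMatrix:
    """Elementwise 50-50 resolution of a harmonized pair."""
    dosages = _DOSE_TABLE[pair.seq.calls, pair.micro.calls]
    prov = _PROV_TABLE[pair.seq.calls, pair.micro.calls]
    return DosageMatrix(pair.rs_ids, pair.samples, dosages, prov)
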