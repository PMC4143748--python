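"""Reading, validating, and harmonizing paired genotype call sets.

Supports three on-disk dialects:

* **VCF 4.x** (optionally gzipped), read with :mod:`cyvcf2`.  REF is taken
  as the major allele and ALT as the minor allele (the reference-allele
  orientation customary for sequencing calls); multiallelic records are
  excluded with a logged reason.
* **PLINK text** ``.ped``/``.map``.  PLINK text carries no allele roles,
  so the major allele is the more frequent allele among called genotypes
  in the file, ties broken alphabetically.
* **Genotype TSV**: header row of sample IDs after five fixed columns
  ``rs_id  chrom  pos  allele_major  allele_minor``; cells in
  {AA, AB, BB, XX}, with NA accepted as missing.  Coordinates are 1-based.

Harmonization matches variants across the two call sets by rs identifier,
classifies each matched allele pair (identical / label-swapped /
strand-flipped / mismatched), re-orients one matrix where the relation is
resolvable, and excludes the rest with per-variant reasons.  By default
any allele-pair difference is an exclusion; strand-flip rescue is opt-in.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gtconcord.calls import (
    AA, AB, BB, XX,
    CALL_LABELS, CODE_OF, COMPLEMENT, VALID_ALLELES,
    decode_calls, encode_calls, is_palindromic,
)

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["rs_id", "chrom", "pos", "allele_major", "allele_minor"]

ORIENTATIONS = ("identical", "swapped", "strand_flip", "strand_flip_swapped")

#: swapped orientation relabels major<->minor homozygotes; XX/AB fixed
_SWAP_RECODE = np.array([BB, AB, AA, XX], dtype=np.int8)


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be parsed as genotypes."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with its (major, minor) allele pair."""

    rs_id: str
    chrom: str
    pos: int
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if not self.rs_id:
            raise ValueError("rs_id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"{self.rs_id}: pos must be >= 1 (1-based)")
        for a in (self.allele_major, self.allele_minor):
            if a not in VALID_ALLELES:
                raise ValueError(f"{self.rs_id}: invalid allele {a!r}")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.rs_id}: major and minor alleles equal")

    @property
    def alleles(self) -> tuple[str, str]:
        return self.allele_major, self.allele_minor


class GenotypeMatrix:
    """Variants x samples matrix of categorical calls {AA, AB, BB, XX}.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``rs_id, chrom, pos,
        allele_major, allele_minor``.
    samples : sequence of str
        Sample identifiers, one per column of ``calls``.
    calls : ndarray of int8, shape (n_variants, n_samples)
        Call codes 0=AA, 1=AB, 2=BB, 3=XX (see :mod:`gtconcord.calls`).
    """

    def __init__(self, variants: pd.DataFrame, samples, calls: np.ndarray):
        variants = variants.reset_index(drop=True)[VARIANT_COLUMNS].copy()
        variants["pos"] = variants["pos"].astype(np.int64)
        samples = list(samples)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(variants), len(samples)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(variants)} variants x {len(samples)} samples"
            )
        if calls.size and (calls.min() < AA or calls.max() > XX):
            raise ValueError("call codes must be in 0..3")
        if variants["rs_id"].duplicated().any():
            dups = variants.loc[variants["rs_id"].duplicated(), "rs_id"]
            raise ValueError(f"duplicate rs_ids: {sorted(set(dups))[:5]} ...")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        for row in variants.itertuples(index=False):
            VariantRecord(row.rs_id, str(row.chrom), int(row.pos),
                          row.allele_major, row.allele_minor)
        self.variants = variants
        self.samples = samples
        self.calls = calls
        self._rs_index = {rs: i for i, rs in enumerate(variants["rs_id"])}

    # -- basic container protocol -------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def rs_ids(self) -> list[str]:
        return list(self.variants["rs_id"])

    def variant_index(self, rs_id: str) -> int:
        return self._rs_index[rs_id]

    def variant_record(self, rs_id: str) -> VariantRecord:
        row = self.variants.iloc[self._rs_index[rs_id]]
        return VariantRecord(row.rs_id, str(row.chrom), int(row.pos),
                             row.allele_major, row.allele_minor)

    def subset(self, rs_ids=None, samples=None) -> "GenotypeMatrix":
        """Restrict to the given variants and/or samples, in the given order."""
        vi = (np.arange(self.n_variants) if rs_ids is None
              else np.array([self._rs_index[r] for r in rs_ids], dtype=np.intp))
        si = (np.arange(self.n_samples) if samples is None
              else np.array([self.samples.index(s) for s in samples],
                            dtype=np.intp))
        return GenotypeMatrix(self.variants.iloc[vi],
                              [self.samples[i] for i in si],
                              self.calls[np.ix_(vi, si)])

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame of labels, indexed by rs_id."""
        return pd.DataFrame(decode_calls(self.calls),
                            index=self.variants["rs_id"], columns=self.samples)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (self.samples == other.samples
                and self.variants.equals(other.variants)
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return (f"<GenotypeMatrix {self.n_variants} variants x "
                f"{self.n_samples} samples>")


@dataclass
class HarmonizedPair:
    """Two sample- and variant-aligned matrices with consistent alleles.

    ``seq`` holds the sequence-platform calls and ``micro`` the microarray
    calls; both share identical variant and sample order.  ``orientation``
    records, per retained variant, the transform that was applied to the
    second matrix; ``exclusions`` lists dropped variants with reasons.
    """

    seq: GenotypeMatrix
    micro: GenotypeMatrix
    orientation: pd.Series
    exclusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["rs_id", "reason", "seq_alleles", "micro_alleles"]))
    n_matched: int = 0

    def __post_init__(self) -> None:
        if self.seq.rs_ids != self.micro.rs_ids:
            raise ValueError("seq/micro variant order differs")
        if self.seq.samples != self.micro.samples:
            raise ValueError("seq/micro sample order differs")
        if self.n_matched == 0:
            self.n_matched = self.seq.n_variants + len(self.exclusions)
        if self.seq.n_variants + len(self.exclusions) != self.n_matched:
            raise ValueError("retained + excluded != matched")

    @property
    def n_variants(self) -> int:
        return self.seq.n_variants

    @property
    def n_samples(self) -> int:
        return self.seq.n_samples

    @property
    def samples(self) -> list[str]:
        return self.seq.samples

    @property
    def rs_ids(self) -> list[str]:
        return self.seq.rs_ids

    def subset(self, rs_ids=None, samples=None) -> "HarmonizedPair":
        return HarmonizedPair(
            seq=self.seq.subset(rs_ids, samples),
            micro=self.micro.subset(rs_ids, samples),
            orientation=(self.orientation if rs_ids is None
                         else self.orientation.loc[list(rs_ids)]),
            exclusions=self.exclusions.iloc[0:0],
        )

    def write_exclusions(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype call set from disk.

    Parameters
    ----------
    path : str or Path
    format : {'vcf', 'plink_text', 'tsv'}
        For ``plink_text`` pass the ``.ped`` path (the ``.map`` is looked
        up next to it) or the common prefix.

    All platform missing codes (VCF ``./.``, PLINK ``0 0``, TSV
    ``XX``/``NA``) map to the single internal missing call ``XX``.
    """
    readers = {"vcf": _read_vcf, "plink_text": _read_plink_text,
               "tsv": _read_tsv}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; "
                         f"expected one of {sorted(readers)}") from None
    return reader(str(path))


def _read_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise GenotypeParseError(f"{path}: cannot parse TSV: {exc}") from exc
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns[:5].tolist()]
    if list(df.columns[:5]) != VARIANT_COLUMNS:
        raise GenotypeParseError(
            f"{path}: first five columns must be {VARIANT_COLUMNS}, "
            f"got {list(df.columns[:5])} (missing {missing_cols})")
    samples = list(df.columns[5:])
    cells = df[samples].to_numpy(dtype=object)
    cells[(cells == "NA") | (cells == "")] = "XX"
    bad = ~np.isin(cells, CALL_LABELS)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: invalid call {cells[i, j]!r} at data line {i + 2}, "
            f"sample {samples[j]!r}")
    variants = df[VARIANT_COLUMNS].copy()
    try:
        variants["pos"] = variants["pos"].astype(np.int64)
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-integer pos: {exc}") from exc
    return GenotypeMatrix(variants, samples, encode_calls(cells))


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:
        raise GenotypeParseError(f"{path}: cannot open VCF: {exc}") from exc
    samples = list(vcf.samples)
    rows, call_rows = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF is None:
            n_multi += 1
            logger.warning("excluding %s: not biallelic (ALT=%s)",
                           v.ID or f"{v.CHROM}:{v.POS}", v.ALT)
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= VALID_ALLELES:
            n_multi += 1
            logger.warning("excluding %s: non-SNP alleles %s/%s",
                           v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT)
            continue
        rs = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}"
        rows.append((rs, str(v.CHROM), int(v.POS), ref, alt))
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown -> matches our codes
        call_rows.append(np.asarray(v.gt_types, dtype=np.int8))
    if not rows:
        raise GenotypeParseError(f"{path}: no usable biallelic SNP records")
    if n_multi:
        logger.info("%s: excluded %d non-biallelic records", path, n_multi)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(variants, samples, np.vstack(call_rows))


def _plink_paths(path: str) -> tuple[str, str]:
    if path.endswith(".ped"):
        return path, path[:-4] + ".map"
    if path.endswith(".map"):
        return path[:-4] + ".ped", path
    return path + ".ped", path + ".map"


def _read_plink_text(path: str) -> GenotypeMatrix:
    ped_path, map_path = _plink_paths(path)
    try:
        vmap = pd.read_csv(map_path, sep=r"\s+", header=None,
                           names=["chrom", "rs_id", "cm", "pos"], dtype=str)
    except Exception as exc:
        raise GenotypeParseError(f"{map_path}: cannot parse .map: {exc}") from exc
    n_var = len(vmap)
    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} fields "
                    f"for {n_var} variants, got {len(fields)}")
            samples.append(fields[1])  # IID
            allele_rows.append(np.array(fields[6:], dtype="U1"))
    if not samples:
        raise GenotypeParseError(f"{ped_path}: no samples")
    alleles = np.stack(allele_rows)  # (n_samples, 2*n_var)
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]  # each (n_samples, n_var)

    variants = []
    calls = np.empty((n_var, len(samples)), dtype=np.int8)
    for j in range(n_var):
        pair = np.stack([a1[:, j], a2[:, j]])  # (2, n_samples)
        called = pair != "0"
        if called.sum() == 0:
            raise GenotypeParseError(
                f"{ped_path}: variant {vmap.rs_id[j]} has no called alleles; "
                "cannot determine major/minor")
        obs, counts = np.unique(pair[called], return_counts=True)
        if not set(obs) <= VALID_ALLELES:
            bad = sorted(set(obs) - VALID_ALLELES)
            raise GenotypeParseError(
                f"{ped_path}: variant {vmap.rs_id[j]}: invalid allele(s) {bad}")
        if len(obs) > 2:
            raise GenotypeParseError(
                f"{ped_path}: variant {vmap.rs_id[j]} has >2 alleles: "
                f"{sorted(obs)}")
        # major = most frequent among called genotypes; ties alphabetical
        order = np.lexsort((obs, -counts))
        major = obs[order[0]]
        minor = obs[order[1]] if len(obs) == 2 else _any_other_allele(major)
        minor_count = (pair == minor).sum(axis=0)
        has_missing = (~called).any(axis=0)
        col = minor_count.astype(np.int8)  # 0,1,2 -> AA,AB,BB
        col[has_missing] = XX
        calls[j] = col
        variants.append((vmap.rs_id[j], vmap.chrom[j], int(vmap.pos[j]),
                         major, minor))
    vdf = pd.DataFrame(variants, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(vdf, samples, calls)


def _any_other_allele(major: str) -> str:
    """Placeholder minor allele for monomorphic PLINK variants."""
    return "A" if major != "A" else "C"


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Write the TSV dialect :func:`read_genotypes` reads back exactly."""
    out = pd.concat(
        [gm.variants.reset_index(drop=True),
         pd.DataFrame(decode_calls(gm.calls), columns=gm.samples)],
        axis=1)
    out.to_csv(path, sep="\t", index=False)


def open_maybe_gzip(path, mode="rt"):
    p = str(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


# ---------------------------------------------------------------------
# matching and harmonization
# ---------------------------------------------------------------------

def match_variants(a: GenotypeMatrix, b: GenotypeMatrix) -> list[str]:
    """rs_ids present in both matrices, ordered as in ``a``.

    Raises ``ValueError`` on an empty intersection (nothing to compare —
    usually a sign the inputs are from different variant panels).
    """
    in_b = set(b.rs_ids)
    matched = [rs for rs in a.rs_ids if rs in in_b]
    if not matched:
        raise ValueError(
            f"no shared rs_ids between call sets "
            f"({a.n_variants} vs {b.n_variants} variants; e.g. "
            f"{a.rs_ids[:3]} vs {b.rs_ids[:3]})")
    logger.info("matched %d variants (%d only in a, %d only in b)",
                len(matched), a.n_variants - len(matched),
                b.n_variants - len(matched))
    return matched


def check_allele_consistency(va: VariantRecord, vb: VariantRecord,
                             allow_strand_flip: bool = False) -> str:
    """Classify the relation between two platforms' allele pairs.

    Returns one of ``identical``, ``swapped``, ``strand_flip``,
    ``strand_flip_swapped``, ``mismatch``, ``ambiguous_palindromic``.
    With ``allow_strand_flip`` off (the default analysis policy) every
    non-{identical, swapped} relation is a ``mismatch``; with it on,
    A/T and C/G sites are flagged ``ambiguous_palindromic`` because a
    strand flip there is indistinguishable from an allele swap.
    """
    if va.rs_id != vb.rs_id:
        raise ValueError(f"rs_id mismatch: {va.rs_id} vs {vb.rs_id}")
    a, b = va.alleles, vb.alleles
    if allow_strand_flip and is_palindromic(*a) and set(a) == set(b):
        return "ambiguous_palindromic"
    if b == a:
        return "identical"
    if b == a[::-1]:
        return "swapped"
    if allow_strand_flip:
        flipped = (COMPLEMENT[a[0]], COMPLEMENT[a[1]])
        if b == flipped:
            return "strand_flip"
        if b == flipped[::-1]:
            return "strand_flip_swapped"
    return "mismatch"


def harmonize(seq: GenotypeMatrix, micro: GenotypeMatrix,
              allow_strand_flip: bool = False,
              keep_palindromic: bool = False) -> HarmonizedPair:
    """Align two call sets on shared samples and allele-consistent variants.

    The second matrix (``micro``) is re-oriented onto the first's allele
    frame: a ``swapped`` relation relabels its AA<->BB calls and swaps its
    allele metadata; a ``strand_flip`` complements its allele metadata and
    leaves calls untouched.  Variants whose allele pairs cannot be
    reconciled under the active policy are excluded with a reason; the
    accounting invariant retained + excluded = matched always holds.

    Parameters
    ----------
    allow_strand_flip : bool
        Off by default: any allele-pair difference beyond a pure label
        swap is an exclusion.  On, C/T-vs-G-A style complement relations
        are rescued and palindromic (A/T, C/G) sites become ambiguous.
    keep_palindromic : bool
        Only meaningful with ``allow_strand_flip``; keeps ambiguous
        palindromic sites, treating them as ``identical``.
    """
    shared = [s for s in seq.samples if s in set(micro.samples)]
    if not shared:
        raise ValueError("no shared samples between call sets")
    n_drop = (seq.n_samples - len(shared)) + (micro.n_samples - len(shared))
    if n_drop:
        logger.info("dropped %d samples present on only one platform", n_drop)

    matched = match_variants(seq, micro)
    retained, orient, excl = [], [], []
    for rs in matched:
        va, vb = seq.variant_record(rs), micro.variant_record(rs)
        if (va.chrom, va.pos) != (vb.chrom, vb.pos):
            logger.warning("%s: position disagreement %s:%d vs %s:%d "
                           "(matched by rs_id; kept)",
                           rs, va.chrom, va.pos, vb.chrom, vb.pos)
        rel = check_allele_consistency(va, vb, allow_strand_flip)
        if rel == "ambiguous_palindromic" and keep_palindromic:
            rel = "identical"
        if rel in ("mismatch", "ambiguous_palindromic"):
            excl.append((rs, rel, "/".join(va.alleles), "/".join(vb.alleles)))
        else:
            retained.append(rs)
            orient.append(rel)

    seq_h = seq.subset(retained, shared)
    micro_h = micro.subset(retained, shared)
    orientation = pd.Series(orient, index=retained, name="orientation")
    _apply_orientation(micro_h, orientation)

    exclusions = pd.DataFrame(
        excl, columns=["rs_id", "reason", "seq_alleles", "micro_alleles"])
    logger.info("harmonize: matched=%d retained=%d excluded=%d",
                len(matched), len(retained), len(excl))
    return HarmonizedPair(seq=seq_h, micro=micro_h, orientation=orientation,
                          exclusions=exclusions, n_matched=len(matched))


def _apply_orientation(gm: GenotypeMatrix, orientation: pd.Series) -> None:
    """Re-orient ``gm`` in place onto the partner matrix's allele frame."""
    for i, rel in enumerate(orientation):
        if rel == "identical":
            continue
        row = gm.variants.iloc[i]
        major, minor = row.allele_major, row.allele_minor
        if rel in ("swapped", "strand_flip_swapped"):
            gm.calls[i] = _SWAP_RECODE[gm.calls[i]]
            major, minor = minor, major
        if rel in ("strand_flip", "strand_flip_swapped"):
            major, minor = COMPLEMENT[major], COMPLEMENT[minor]
        gm.variants.iloc[i, gm.variants.columns.get_loc("allele_major")] = major
        gm.variants.iloc[i, gm.variants.columns.get_loc("allele_minor")] = minor
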