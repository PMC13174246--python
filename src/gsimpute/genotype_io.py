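"""Genotype containers, file dialects and marker-set algebra.

Genotypes are held as integer codes in a samples x markers matrix:

    0  missing
    1  A1A1 (homozygous reference)
    2  A1A2 (heterozygous, phase ignored)
    3  A2A2 (homozygous alternate)

Markers are identified by their (chromosome, position) key throughout; all
set operations (union/intersection of chip designs against a reference
panel) work on those keys.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerRecord",
    "GenotypeMatrix",
    "PositionSet",
    "read_vcf",
    "read_csv_genotypes",
    "read_positions",
    "write_integer_genotypes",
    "encode_onehot",
    "decode_onehot",
    "marker_set_op",
    "subset_panel",
    "segment_chromosome",
]

MISSING = 0
VALID_CODES = frozenset({0, 1, 2, 3})


@dataclass(frozen=True)
class MarkerRecord:
    """A biallelic SNP: A1 = ref (matches the reference genome), A2 = alt."""

    chrom: str
    pos: int
    id: str | None = None
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class GenotypeMatrix:
    """Integer-coded genotypes for an ordered set of samples and markers.

    Parameters
    ----------
    sample_ids : ordered sample labels.
    markers : ordered MarkerRecord sequence, sorted by (chrom, pos) with
        strictly increasing positions within each chromosome.
    codes : (n_samples, n_markers) integer array with entries in {0,1,2,3}.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        markers: Sequence[MarkerRecord],
        codes: np.ndarray,
        validate: bool = True,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.markers = list(markers)
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x markers)")
        if codes.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"codes shape {codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        self.codes = codes
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        last: dict[str, int] = {}
        seen_order: list[str] = []
        for m in self.markers:
            if m.chrom in last:
                if m.pos <= last[m.chrom]:
                    raise ValueError(
                        f"markers not strictly increasing within chromosome "
                        f"{m.chrom} at position {m.pos}"
                    )
                if seen_order[-1] != m.chrom:
                    raise ValueError(f"chromosome {m.chrom} appears in non-contiguous blocks")
            else:
                seen_order.append(m.chrom)
            last[m.chrom] = m.pos

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_markers)

    def keys(self) -> list[tuple[str, int]]:
        return [m.key for m in self.markers]

    def position_set(self) -> "PositionSet":
        return PositionSet(self.keys())

    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def missing_rate(self) -> float:
        return float((self.codes == MISSING).mean()) if self.codes.size else 0.0

    # -- slicing -------------------------------------------------------
    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        markers = [self.markers[i] for i in index]
        return GenotypeMatrix(self.sample_ids, markers, self.codes[:, index], validate=False)

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        ids = [self.sample_ids[i] for i in index]
        return GenotypeMatrix(ids, self.markers, self.codes[index], validate=False)

    def marker_slice(self, start: int, stop: int) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids, self.markers[start:stop], self.codes[:, start:stop], validate=False
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.markers), self.codes.copy(), validate=False
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_markers} markers>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.codes, other.codes)
        )


def concat_markers(parts: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate marker-wise slices of the same sample set back together."""
    if not parts:
        raise ValueError("nothing to concatenate")
    ids = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != ids:
            raise ValueError("sample sets differ between slices")
    markers = [m for p in parts for m in p.markers]
    codes = np.concatenate([p.codes for p in parts], axis=1)
    return GenotypeMatrix(ids, markers, codes)


class PositionSet:
    """An unordered set of (chrom, pos) marker keys, closed under set algebra."""

    def __init__(self, keys: Iterable[tuple[str, int]] = ()) -> None:
        self.keys = frozenset((str(c), int(p)) for c, p in keys)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (str(key[0]), int(key[1])) in self.keys

    def __or__(self, other: "PositionSet") -> "PositionSet":
        return PositionSet(self.keys | other.keys)

    def __and__(self, other: "PositionSet") -> "PositionSet":
        return PositionSet(self.keys & other.keys)

    def __sub__(self, other: "PositionSet") -> "PositionSet":
        return PositionSet(self.keys - other.keys)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionSet):
            return NotImplemented
        return self.keys == other.keys

    def __hash__(self) -> int:
        return hash(self.keys)

    def sorted(self) -> list[tuple[str, int]]:
        return sorted(self.keys)

    def __repr__(self) -> str:
        return f"<PositionSet of {len(self.keys)} loci>"


def marker_set_op(a: PositionSet, b: PositionSet, op: str) -> PositionSet:
    """Union or intersection of two marker position sets."""
    if op == "union":
        return a | b
    if op == "intersection":
        return a & b
    raise ValueError(f"unknown set operation {op!r}")


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf(path: str, chrom_filter: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF file.

    GT calls map to codes: 0/0 -> 1, 0/1 or 1/0 (phased or not) -> 2,
    1/1 -> 3, any missing allele -> 0. Non-biallelic and non-SNP records
    are skipped with a warning; duplicate (chrom, pos) keys keep the first
    occurrence.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF contains no samples")

    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    n_skipped = n_dup = 0
    for var in vcf:
        chrom = str(var.CHROM)
        if chrom_filter is not None and chrom != str(chrom_filter):
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        key = (chrom, int(var.POS))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        codes = np.where(gt == 3, 0, gt + 1).astype(np.int8)
        markers.append(
            MarkerRecord(chrom, int(var.POS), var.ID or None, var.REF, var.ALT[0])
        )
        rows.append(codes)
    vcf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-biallelic/non-SNP records")
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate (chrom,pos) records")
    if not markers:
        raise ValueError(f"{path}: no biallelic SNP records found")
    codes = np.stack(rows, axis=1)
    return GenotypeMatrix(sample_ids, markers, codes)  # validates sortedness


# ---------------------------------------------------------------------------
# CSV / TXT genotype dialect
# ---------------------------------------------------------------------------

_SENTINELS = ("ref", "alt", "qccode")
_CHROM_ALIASES = {"chrom", "chr", "#chrom", "chromosome"}
_POS_ALIASES = {"pos", "position", "bp"}
_ID_ALIASES = {"id", "rs", "rs#", "marker", "snp", "name"}


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_csv_genotypes(path: str) -> GenotypeMatrix:
    """Read a marker-rows x sample-columns integer genotype table.

    The header column immediately preceding the genotype block must be
    named ``ref``, ``alt`` or ``QCcode`` (case-insensitive); every column
    to its right is a sample. Metadata columns must include the chromosome
    and position; genotype cells must already be coded 0/1/2/3.
    """
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str)
    headers = [str(h).strip() for h in df.columns]
    lowered = [h.lower() for h in headers]

    sentinel_idx = max(
        (i for i, h in enumerate(lowered) if h in _SENTINELS), default=-1
    )
    if sentinel_idx < 0:
        raise ValueError(
            f"{path}: no sentinel column (ref/alt/QCcode) found before the genotype block"
        )
    sample_cols = headers[sentinel_idx + 1 :]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns after sentinel {headers[sentinel_idx]!r}")

    def find(aliases: set[str]) -> int | None:
        for i, h in enumerate(lowered[: sentinel_idx + 1]):
            if h in aliases:
                return i
        return None

    ci = find(_CHROM_ALIASES)
    pi = find(_POS_ALIASES)
    if ci is None or pi is None:
        raise ValueError(f"{path}: chromosome/position metadata columns not found")
    ri = find({"ref"})
    ai = find({"alt"})
    ii = find(_ID_ALIASES)

    geno = df.iloc[:, sentinel_idx + 1 :].to_numpy()
    try:
        codes = geno.astype(np.int16)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer genotype cell: {exc}") from None
    bad = set(np.unique(codes)) - VALID_CODES
    if bad:
        raise ValueError(f"{path}: genotype cells outside {{0,1,2,3}}: {sorted(bad)}")

    markers: list[MarkerRecord] = []
    keep: list[int] = []
    seen: set[tuple[str, int]] = set()
    n_dup = 0
    for r in range(len(df)):
        chrom = str(df.iat[r, ci]).strip()
        pos = int(df.iat[r, pi])
        if (chrom, pos) in seen:
            n_dup += 1
            continue
        seen.add((chrom, pos))
        ref = str(df.iat[r, ri]).strip() if ri is not None else "A"
        alt = str(df.iat[r, ai]).strip() if ai is not None else "G"
        mid = str(df.iat[r, ii]).strip() if ii is not None else None
        markers.append(MarkerRecord(chrom, pos, mid, ref, alt))
        keep.append(r)
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate (chrom,pos) rows")
    return GenotypeMatrix(sample_cols, markers, codes[keep].T.astype(np.int8))


def read_positions(path: str) -> PositionSet:
    """Read a marker position file: two-column chrom/pos text, or any
    genotype file (VCF or the CSV dialect), whose loci are extracted."""
    lower = path.lower()
    if lower.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path).position_set()
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str)
    lowered = [str(h).strip().lower() for h in df.columns]
    if any(h in _SENTINELS for h in lowered):
        return read_csv_genotypes(path).position_set()
    ci = next((i for i, h in enumerate(lowered) if h in _CHROM_ALIASES), 0)
    pi = next((i for i, h in enumerate(lowered) if h in _POS_ALIASES), 1)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: position file needs chromosome and position columns")
    return PositionSet(
        (str(df.iat[r, ci]).strip(), int(df.iat[r, pi])) for r in range(len(df))
    )


def write_integer_genotypes(g: GenotypeMatrix, path: str, sep: str = ",") -> None:
    """Write a fully imputed matrix as the marker-rows integer table.

    Refuses residual missing codes: imputation output is complete by
    contract. Re-reading the file with read_csv_genotypes round-trips.
    """
    if g.has_missing():
        n = int((g.codes == MISSING).sum())
        raise ValueError(f"matrix still contains {n} missing (code 0) entries")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["chrom", "pos", "id", "ref", "alt", *g.sample_ids])
        for j, m in enumerate(g.markers):
            w.writerow([m.chrom, m.pos, m.id or ".", m.ref, m.alt, *g.codes[:, j].tolist()])


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def encode_onehot(codes: np.ndarray | GenotypeMatrix) -> np.ndarray:
    """One-hot encode integer genotype codes.

    0 -> [0,0,0] (missing), 1 -> [1,0,0], 2 -> [0,1,0], 3 -> [0,0,1].
    Returns a float32 array of shape (samples, markers, 3).
    """
    if isinstance(codes, GenotypeMatrix):
        codes = codes.codes
    codes = np.asarray(codes)
    bad = set(np.unique(codes)) - VALID_CODES
    if bad:
        raise ValueError(f"invalid genotype codes: {sorted(bad)}")
    out = np.zeros((*codes.shape, 3), dtype=np.float32)
    for c in (1, 2, 3):
        out[..., c - 1][codes == c] = 1.0
    return out


def decode_onehot(block: np.ndarray) -> np.ndarray:
    """Invert encode_onehot: all-zero channel vectors decode to 0 (missing)."""
    block = np.asarray(block)
    if block.shape[-1] != 3:
        raise ValueError("last axis must have 3 genotype channels")
    present = block.sum(axis=-1) > 0
    return np.where(present, block.argmax(axis=-1) + 1, 0).astype(np.int8)


# ---------------------------------------------------------------------------
# Panel subsetting and chromosome segmentation
# ---------------------------------------------------------------------------

def subset_panel(
    panel: GenotypeMatrix,
    targets: PositionSet,
    target_markers: Sequence[MarkerRecord] | None = None,
) -> GenotypeMatrix:
    """Restrict a missing-free reference panel to the target loci.

    When the target's MarkerRecords are supplied, loci whose (ref, alt)
    alleles disagree with the panel (including swapped alleles) are
    dropped with a warning rather than flipped.
    """
    if panel.has_missing():
        raise ValueError("missing genotypes are not permitted in the reference panel")
    allele_of = (
        {m.key: (m.ref, m.alt) for m in target_markers} if target_markers is not None else {}
    )
    keep: list[int] = []
    n_mismatch = 0
    for j, m in enumerate(panel.markers):
        if m.key not in targets:
            continue
        want = allele_of.get(m.key)
        if want is not None and want != (m.ref, m.alt):
            n_mismatch += 1
            continue
        keep.append(j)
    if n_mismatch:
        warnings.warn(f"dropped {n_mismatch} loci with mismatched ref/alt alleles")
    if not keep:
        raise ValueError("no overlap between panel loci and target positions")
    return panel.subset_markers(keep)


def segment_chromosome(g: GenotypeMatrix, max_markers: int) -> list[GenotypeMatrix]:
    """Split into contiguous marker slices of at most max_markers each.

    Concatenating the slices in order reproduces the input exactly.
    """
    if max_markers < 1:
        raise ValueError("max_markers must be >= 1")
    return [g.marker_slice(s, min(s + max_markers, g.n_markers))
            for s in range(0, g.n_markers, max_markers)] or [g]
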