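"""Clonotype table reading, validation, collapsing, and VJ partitioning.

Tables are tab-separated with a header row (VDJtools-style by default:
``count  freq  cdr3nt  cdr3aa  v  j``).  A :class:`Dialect` maps those roles
onto other conventions (e.g. MiXCR exports).  Clonotype calling is upstream;
this module never touches raw reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .seqs import is_canonical_aa, translate

logger = logging.getLogger(__name__)

FREQ_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Malformed clonotype table."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a clonotype table."""

    count: str = "count"
    freq: str = "freq"
    cdr3nt: str = "cdr3nt"
    cdr3aa: str = "cdr3aa"
    v: str = "v"
    j: str = "j"
    #: strip allele suffixes like "*01" from V/J names (gene-level classes)
    strip_alleles: bool = True


VDJTOOLS = Dialect()
MIXCR = Dialect(
    count="cloneCount",
    freq="cloneFraction",
    cdr3nt="nSeqCDR3",
    cdr3aa="aaSeqCDR3",
    v="allVHitsWithScore",
    j="allJHitsWithScore",
)

DIALECTS = {"vdjtools": VDJTOOLS, "mixcr": MIXCR}


@dataclass(frozen=True)
class Clonotype:
    """One nucleotide-level TCR rearrangement."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    read_count: int
    frequency: float | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cdr3_nt, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """An ordered collection of clonotypes from one sample."""

    clonotypes: list[Clonotype]
    sample_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes)

    def with_frequencies(self) -> "Repertoire":
        """Fill missing frequencies from read counts (existing ones trusted)."""
        if all(c.frequency is not None for c in self.clonotypes):
            return self
        total = self.total_reads
        clons = [
            c if c.frequency is not None else replace(c, frequency=c.read_count / total)
            for c in self.clonotypes
        ]
        return Repertoire(clons, self.sample_id, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        rep = self.with_frequencies() if self.clonotypes else self
        return pd.DataFrame(
            {
                "count": [c.read_count for c in rep.clonotypes],
                "freq": [c.frequency for c in rep.clonotypes],
                "cdr3nt": [c.cdr3_nt for c in rep.clonotypes],
                "cdr3aa": [c.cdr3_aa for c in rep.clonotypes],
                "v": [c.v_gene for c in rep.clonotypes],
                "j": [c.j_gene for c in rep.clonotypes],
            }
        )


@dataclass
class VJClass:
    """All clonotypes of a repertoire sharing one (V, J) combination."""

    v_gene: str
    j_gene: str
    members: list[Clonotype]

    @property
    def vj(self) -> tuple[str, str]:
        return (self.v_gene, self.j_gene)

    @property
    def n(self) -> int:
        """Number of unique nucleotide clonotypes in the class."""
        return len(self.members)


def _strip_allele(name: str) -> str:
    return name.split("*", 1)[0].strip()


def read_clonotype_table(
    path: str | Path,
    dialect: Dialect | str = VDJTOOLS,
    sample_id: str | None = None,
    on_translation_mismatch: str = "reject",
) -> Repertoire:
    """Read and validate a tab-separated clonotype table.

    Rows whose amino-acid CDR3 contains characters outside the 20 canonical
    letters (stops, 'X', '_') are excluded from the analysis set but counted
    in ``provenance['excluded_noncanonical']``.  Rows where the in-frame
    translation of the nucleotide CDR3 disagrees with the stated amino-acid
    CDR3 are rejected (``on_translation_mismatch='reject'``, the default and
    counted) or kept as-is (``'ignore'``).

    Raises :class:`FormatError` when a required column is missing and an
    empty-input error when the table has no rows.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "count": dialect.count,
        "cdr3nt": dialect.cdr3nt,
        "cdr3aa": dialect.cdr3aa,
        "v": dialect.v,
        "j": dialect.j,
    }
    for role, col in required.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} ({role})")
    if df.empty:
        raise FormatError(f"{path}: table has no data rows")
    has_freq = dialect.freq in df.columns

    clonotypes: list[Clonotype] = []
    excluded_noncanonical = 0
    excluded_malformed = 0
    excluded_mismatch = 0
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        try:
            count = int(float(rec[dialect.count]))
            nt = str(rec[dialect.cdr3nt]).upper()
            aa = str(rec[dialect.cdr3aa])
            v = str(rec[dialect.v])
            j = str(rec[dialect.j])
            if dialect.strip_alleles:
                v, j = _strip_allele(v), _strip_allele(j)
            freq = float(rec[dialect.freq]) if has_freq else None
        except (TypeError, ValueError):
            excluded_malformed += 1
            continue
        if count < 1 or not nt:
            excluded_malformed += 1
            continue
        if not is_canonical_aa(aa):
            excluded_noncanonical += 1
            continue
        if len(nt) % 3 == 0 and on_translation_mismatch == "reject":
            try:
                if translate(nt) != aa:
                    excluded_mismatch += 1
                    continue
            except ValueError:
                excluded_malformed += 1
                continue
        clonotypes.append(Clonotype(nt, aa, v, j, count, freq))

    rep = Repertoire(
        clonotypes,
        sample_id=sample_id or path.stem,
        provenance={
            "path": str(path),
            "rows_read": int(len(df)),
            "excluded_noncanonical": excluded_noncanonical,
            "excluded_malformed": excluded_malformed,
            "excluded_translation_mismatch": excluded_mismatch,
        },
    )
    freq_sum = sum(c.frequency for c in clonotypes if c.frequency is not None)
    if freq_sum > 1 + FREQ_SUM_TOL:
        logger.warning("%s: frequencies sum to %.6f > 1", path, freq_sum)
    logger.info(
        "%s: %d rows read, %d kept, %d non-canonical, %d malformed, %d mistranslated",
        path, len(df), len(clonotypes), excluded_noncanonical,
        excluded_malformed, excluded_mismatch,
    )
    return rep


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire back out in the default (VDJtools-style) dialect."""
    rep.to_frame().to_csv(path, sep="\t", index=False)


def collapse_germline_errors(rep: Repertoire) -> Repertoire:
    """Merge clonotypes sharing (cdr3_nt, V, J), summing read counts.

    Sequencing errors in the germline-encoded region can split one true
    clonotype into several V/J-call duplicates; collapsing restores a
    key-unique table.  Idempotent; output is sorted canonically
    (by V, J, CDR3nt) so the result is order-independent.
    """
    merged: dict[tuple[str, str, str], Clonotype] = {}
    for c in rep.clonotypes:
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = c
        else:
            freq = (
                None
                if prev.frequency is None or c.frequency is None
                else prev.frequency + c.frequency
            )
            merged[c.key] = replace(
                prev, read_count=prev.read_count + c.read_count, frequency=freq
            )
    out = sorted(merged.values(), key=lambda c: (c.v_gene, c.j_gene, c.cdr3_nt))
    prov = dict(rep.provenance)
    prov["collapsed_rows"] = len(rep.clonotypes) - len(out)
    return Repertoire(out, rep.sample_id, prov)


def partition_by_vj(rep: Repertoire) -> list[VJClass]:
    """Partition a collapsed repertoire into its (V, J) classes.

    Every clonotype lands in exactly one class; class sizes sum to the
    repertoire size.  Classes are returned sorted by (V, J).
    """
    groups: dict[tuple[str, str], list[Clonotype]] = {}
    for c in rep.clonotypes:
        groups.setdefault((c.v_gene, c.j_gene), []).append(c)
    return [
        VJClass(v, j, members) for (v, j), members in sorted(groups.items())
    ]
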