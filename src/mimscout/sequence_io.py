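"""Reading and writing of the sequence formats used across the pipeline.

Protein sequences travel as :class:`SequenceRecord` (plain FASTA), multiple
sequence alignments as :class:`AlignedSet` (aligned FASTA, ``-`` gaps), and
assigned C-alpha chemical shifts as :class:`ShiftTable` (tab-separated, with
``#temperature_C=`` / ``#pH=`` metadata lines).

Taxonomic metadata is carried as a single order-level tag in the FASTA
description (``taxon=<Order>``, e.g. ``taxon=Brassicales``), which is all the
downstream taxonomy-restricted search needs.  All coordinates in files and
reports are 1-based and inclusive on both ends.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "CANONICAL_RESIDUES",
    "GAP",
    "MASK",
    "SequenceRecord",
    "AlignedSet",
    "ShiftTable",
    "FastaParseError",
    "NonCanonicalResidueError",
    "RaggedAlignmentError",
    "ShiftTableError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_shift_table",
]

log = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Gap symbol used in alignments.
GAP = "-"

#: Masking symbol substituted for non-canonical residues under policy "mask".
#: Masked positions never take part in a motif match.
MASK = "X"

_TAXON_RE = re.compile(r"\btaxon=(\S+)")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class NonCanonicalResidueError(ValueError):
    """Raised under policy ``strict`` when a sequence contains non-canonical letters."""


class RaggedAlignmentError(ValueError):
    """Raised when aligned FASTA entries do not share one length."""


class ShiftTableError(ValueError):
    """Raised for malformed chemical-shift tables."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an identifier and optional order-level taxon tag.

    ``residues`` holds uppercase canonical one-letter codes; under the ``mask``
    input policy it may additionally contain :data:`MASK`.  Empty sequences are
    representable (``is_empty``) but flagged with a warning on input.
    """

    identifier: str
    residues: str
    description: str = ""
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("SequenceRecord identifier must be non-empty")
        # Gap symbols are tolerated here so records can live inside an
        # AlignedSet; plain FASTA input never produces them.
        bad = sorted(set(self.residues) - _CANONICAL_SET - {MASK, GAP})
        if bad:
            raise NonCanonicalResidueError(
                f"record {self.identifier!r}: non-canonical residue(s) {''.join(bad)!r}"
            )

    @property
    def is_empty(self) -> bool:
        return len(self.residues) == 0

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSet:
    """An alignment: equal-length records whose residues may include gaps."""

    records: tuple["SequenceRecord", ...]
    column_count: int

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.residues) != self.column_count:
                raise RaggedAlignmentError(
                    f"record {rec.identifier!r} has length {len(rec.residues)}, "
                    f"expected {self.column_count}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def degapped(self) -> list[SequenceRecord]:
        """Remove gap symbols, recovering plain :class:`SequenceRecord` objects."""
        return [replace(r, residues=r.residues.replace(GAP, "")) for r in self.records]

    def column(self, index: int) -> str:
        """Return alignment column ``index`` (0-based) as a string."""
        return "".join(r.residues[index] for r in self.records)


@dataclass(frozen=True)
class ShiftTable:
    """Assigned C-alpha chemical shifts with acquisition conditions.

    ``rows`` is a DataFrame with columns ``residue_index`` (1-based, strictly
    increasing), ``residue_code`` and ``ca_shift_ppm``.  Defaults for the
    conditions follow the acquisition setup of the motif peptides (5 degC,
    pH 7.0).
    """

    rows: pd.DataFrame
    temperature_C: float = 5.0
    pH: float = 7.0

    def __post_init__(self) -> None:
        idx = self.rows["residue_index"].to_numpy()
        if len(idx) and not (idx[1:] > idx[:-1]).all():
            raise ShiftTableError("residue_index must be strictly increasing")
        shifts = self.rows["ca_shift_ppm"].to_numpy()
        out = (shifts < 40.0) | (shifts > 75.0)
        if out.any():
            bad = self.rows.loc[out, "residue_index"].tolist()
            raise ShiftTableError(
                f"ca_shift_ppm outside the 40-75 ppm sanity window at residue_index {bad}"
            )

    def __len__(self) -> int:
        return len(self.rows)


def _check_fasta_structure(text: str) -> None:
    """Reject sequence data appearing before any FASTA header, naming the line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(";"):
            continue
        if stripped.startswith(">"):
            return
        raise FastaParseError(
            f"sequence data before any FASTA header at line {lineno}: {stripped[:40]!r}"
        )


def _apply_policy(identifier: str, residues: str, policy: str) -> str:
    bad = sorted(set(residues) - _CANONICAL_SET)
    if not bad:
        return residues
    if policy == "strict":
        raise NonCanonicalResidueError(
            f"record {identifier!r}: non-canonical residue(s) {''.join(bad)!r} "
            "(use policy='mask' to replace them with X)"
        )
    if policy == "mask":
        table = str.maketrans({c: MASK for c in bad})
        return residues.translate(table)
    raise ValueError(f"unknown residue policy {policy!r}; expected 'strict' or 'mask'")


def _split_description(bio_record) -> tuple[str, Optional[str]]:
    """Return (description-without-taxon-token, taxon) from a Bio.SeqRecord."""
    desc = bio_record.description
    if desc.startswith(bio_record.id):
        desc = desc[len(bio_record.id):].strip()
    m = _TAXON_RE.search(desc)
    taxon = m.group(1) if m else None
    if m:
        desc = (desc[: m.start()] + desc[m.end():]).strip()
    return desc, taxon


def read_fasta(path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased and ``*`` stop symbols stripped.  A
    ``taxon=<name>`` key in the description populates the record's taxon.

    Parameters
    ----------
    policy:
        ``"strict"`` (default) raises :class:`NonCanonicalResidueError` on any
        non-canonical residue letter; ``"mask"`` replaces such letters with
        ``X``, which downstream scanning never matches.
    """
    text = Path(path).read_text()
    if text.strip():
        _check_fasta_structure(text)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(io.StringIO(text), "fasta"):
        if bio.id in seen:
            raise FastaParseError(f"duplicate identifier {bio.id!r}")
        seen.add(bio.id)
        residues = str(bio.seq).upper().replace("*", "")
        residues = _apply_policy(bio.id, residues, policy)
        desc, taxon = _split_description(bio)
        rec = SequenceRecord(identifier=bio.id, residues=residues,
                             description=desc, taxon=taxon)
        if rec.is_empty:
            log.warning("record %r has an empty sequence", rec.identifier)
        records.append(rec)
    return records


def _to_bio(rec: SequenceRecord) -> _BioSeqRecord:
    parts = [rec.description] if rec.description else []
    if rec.taxon is not None:
        parts.append(f"taxon={rec.taxon}")
    return _BioSeqRecord(Seq(rec.residues), id=rec.identifier,
                         description=" ".join(parts))


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as 60-column-wrapped FASTA (taxon re-emitted as ``taxon=``)."""
    SeqIO.write([_to_bio(r) for r in records], str(path), "fasta")


def read_alignment(path, policy: str = "strict") -> AlignedSet:
    """Read an aligned FASTA file; ``.`` gaps are normalized to ``-``.

    Raises :class:`RaggedAlignmentError` naming the two offending identifiers
    when entries differ in length.
    """
    text = Path(path).read_text()
    if text.strip():
        _check_fasta_structure(text)
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(bio.seq).upper().replace("*", "").replace(".", GAP)
        degapped = residues.replace(GAP, "")
        _apply_policy(bio.id, degapped, policy)
        if policy == "mask":
            masked = _apply_policy(bio.id, degapped, "mask")
            it = iter(masked)
            residues = "".join(GAP if c == GAP else next(it) for c in residues)
        desc, taxon = _split_description(bio)
        records.append(SequenceRecord(identifier=bio.id, residues=residues,
                                      description=desc, taxon=taxon))
    if not records:
        raise FastaParseError(f"no alignment records in {path}")
    first = records[0]
    for rec in records[1:]:
        if len(rec.residues) != len(first.residues):
            raise RaggedAlignmentError(
                f"ragged alignment: {first.identifier!r} has length "
                f"{len(first.residues)} but {rec.identifier!r} has length "
                f"{len(rec.residues)}"
            )
    return AlignedSet(records=tuple(records), column_count=len(first.residues))


def write_alignment(aln: AlignedSet, path) -> None:
    """Write an :class:`AlignedSet` as 60-column-wrapped aligned FASTA."""
    SeqIO.write([_to_bio(r) for r in aln.records], str(path), "fasta")


_REQUIRED_SHIFT_COLUMNS = ("residue_index", "residue_code", "ca_shift_ppm")
_META_RE = re.compile(r"#\s*(temperature_C|pH)\s*=\s*(\S+)")


def read_shift_table(path) -> ShiftTable:
    """Read a tab-separated C-alpha chemical-shift table.

    The file holds an optional block of ``#temperature_C=...`` / ``#pH=...``
    metadata lines (defaults: 5 degC, pH 7.0), then a header line naming the
    three columns ``residue_index``, ``residue_code``, ``ca_shift_ppm``.  Rows
    with a missing shift are skipped with a warning; duplicate or decreasing
    residue indices are an error.
    """
    meta = {"temperature_C": 5.0, "pH": 7.0}
    body_lines: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#"):
            m = _META_RE.search(line)
            if m:
                meta[m.group(1)] = float(m.group(2))
            continue
        body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    missing = [c for c in _REQUIRED_SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ShiftTableError(f"shift table missing column(s) {missing}")
    df = df.loc[:, list(_REQUIRED_SHIFT_COLUMNS)]
    blank = df["ca_shift_ppm"].isna()
    if blank.any():
        log.warning("skipping %d shift row(s) with missing ca_shift_ppm "
                    "(residue_index %s)", int(blank.sum()),
                    df.loc[blank, "residue_index"].tolist())
        df = df.loc[~blank]
    df = df.reset_index(drop=True)
    df["residue_index"] = df["residue_index"].astype(int)
    df["residue_code"] = df["residue_code"].astype(str).str.upper()
    df["ca_shift_ppm"] = df["ca_shift_ppm"].astype(float)
    idx = df["residue_index"].to_numpy()
    if len(idx) and not (idx[1:] > idx[:-1]).all():
        raise ShiftTableError("duplicate or decreasing residue_index in shift table")
    bad = sorted(set(df["residue_code"]) - _CANONICAL_SET)
    if bad:
        raise ShiftTableError(f"non-canonical residue code(s) {bad} in shift table")
    return ShiftTable(rows=df, temperature_C=meta["temperature_C"], pH=meta["pH"])
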