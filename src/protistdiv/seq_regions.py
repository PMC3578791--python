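"""Aligned-FASTA I/O, primer-delimited region extraction, and length filtering.

Alignments are grouped by taxon: one multi-FASTA alignment per taxonomic
group, gap character ``'-'``. Sequences are normalized on read (uppercased,
RNA ``U`` mapped to ``T``); IUPAC ambiguity codes are retained and handled
downstream by pairwise deletion. Coordinates in the public API are 1-based
inclusive, the convention of primer position tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from protistdiv.errors import AlignmentError, InputError, RegionError

logger = logging.getLogger(__name__)

GAP = "-"

#: IUPAC nucleotide code -> set of unambiguous bases it stands for.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer given as an IUPAC nucleotide string.

    Parameters
    ----------
    name:
        Primer label, e.g. ``"TAReuk454FWD1"``.
    iupac:
        Primer sequence over IUPAC codes; degeneracies allowed
        (e.g. ``"CCAGCASCYGCGGTAATTCC"``).
    reference_span:
        Optional 1-based inclusive positions on a reference sequence, for
        bookkeeping only.
    """

    name: str
    iupac: str
    reference_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.iupac:
            raise InputError(f"primer {self.name!r}: empty sequence")
        bad = set(self.iupac.upper()) - set(IUPAC_EXPANSION)
        if bad:
            raise InputError(
                f"primer {self.name!r}: invalid IUPAC letters {sorted(bad)}"
            )
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass
class GroupAlignment:
    """An aligned set of sequences belonging to one taxonomic group.

    Invariants (enforced on construction): all rows have identical length
    >= 1; names are unique; region intervals lie within the alignment and
    have start <= end (1-based inclusive).
    """

    group_id: str
    names: list[str]
    rows: list[str]
    region_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError(
                f"group {self.group_id!r}: {len(self.names)} names for "
                f"{len(self.rows)} rows"
            )
        length = len(self.rows[0]) if self.rows else 0
        if self.rows and length < 1:
            raise AlignmentError(f"group {self.group_id!r}: zero-length rows")
        for name, row in zip(self.names, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"group {self.group_id!r}: row {name!r} has length "
                    f"{len(row)}, expected {length}"
                )
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise InputError(
                f"group {self.group_id!r}: duplicate sequence names {sorted(dupes)}"
            )
        for rname, (start, end) in self.region_map.items():
            if not (1 <= start <= end <= length):
                raise RegionError(
                    f"group {self.group_id!r}: region {rname!r} interval "
                    f"[{start}, {end}] outside [1, {length}]"
                )

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise InputError(
                f"group {self.group_id!r}: no sequence named {name!r}"
            ) from None


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path, group_id: str) -> GroupAlignment:
    """Read a multi-FASTA alignment into a :class:`GroupAlignment`.

    Rows are uppercased and ``U`` is mapped to ``T``. Records may be
    line-wrapped. Raises :class:`AlignmentError` on unequal row lengths,
    :class:`InputError` on duplicate names or an empty file.
    """
    names: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    if not rows:
        raise InputError(f"{path}: no FASTA records")
    return GroupAlignment(group_id=group_id, names=names, rows=rows)


def write_alignment(aln: GroupAlignment, path: str | Path, wrap: int = 80) -> None:
    """Write an alignment as multi-FASTA, wrapped at ``wrap`` columns."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(records)


def _primer_regex(primer: PrimerSpec) -> re.Pattern[str]:
    parts = []
    for ch in primer.iupac:
        bases = IUPAC_EXPANSION[ch]
        parts.append(next(iter(bases)) if len(bases) == 1 else f"[{''.join(sorted(bases))}]")
    return re.compile("".join(parts))


def locate_primer(seq: str, primer: PrimerSpec) -> Optional[tuple[int, int]]:
    """First exact IUPAC-compatible match of ``primer`` in ungapped ``seq``.

    A degenerate primer position matches any base in its expansion; no
    mismatches are tolerated. Returns a 1-based inclusive interval, or
    ``None`` if the primer is absent.
    """
    m = _primer_regex(primer).search(_normalize(seq))
    if m is None:
        return None
    return (m.start() + 1, m.end())


def _ungapped_to_columns(row: str) -> list[int]:
    """0-based alignment column for each ungapped position of ``row``."""
    return [i for i, ch in enumerate(row) if ch != GAP]


def extract_region(
    aln: GroupAlignment,
    region: tuple[int, int] | None = None,
    *,
    forward: PrimerSpec | None = None,
    reverse: PrimerSpec | None = None,
    reference: str | None = None,
    drop_primers: bool = False,
    region_name: str | None = None,
) -> GroupAlignment:
    """Extract a sub-alignment, by column interval or by primer pair.

    ``region`` is a 1-based inclusive alignment-column interval. Alternatively
    give ``forward``/``reverse`` primers and the name of a ``reference`` row:
    the primers are located on the ungapped reference and mapped back to
    alignment columns. With ``drop_primers``, the columns matching the
    primers themselves are excluded (the region between them is kept).
    """
    if region is not None:
        start, end = region
        if not (1 <= start <= end <= aln.length):
            raise RegionError(
                f"region [{start}, {end}] invalid for alignment of length {aln.length}"
            )
        col0, col1 = start - 1, end - 1  # inclusive, 0-based
    else:
        if forward is None or reverse is None or reference is None:
            raise InputError(
                "extract_region needs either a column interval or "
                "forward+reverse primers with a reference row name"
            )
        ref_row = aln.row(reference)
        cols = _ungapped_to_columns(ref_row)
        ungapped = ref_row.replace(GAP, "")
        fwd = locate_primer(ungapped, forward)
        if fwd is None:
            raise RegionError(
                f"primer {forward.name!r} not found on reference {reference!r}"
            )
        rev = locate_primer(ungapped, reverse)
        if rev is None:
            raise RegionError(
                f"primer {reverse.name!r} not found on reference {reference!r}"
            )
        if drop_primers:
            u0, u1 = fwd[1], rev[0] - 2  # first base after fwd .. last before rev
        else:
            u0, u1 = fwd[0] - 1, rev[1] - 1
        if u0 > u1:
            raise RegionError(
                f"primers {forward.name!r}/{reverse.name!r} delimit an empty region"
            )
        col0, col1 = cols[u0], cols[u1]
    new_rows = [row[col0 : col1 + 1] for row in aln.rows]
    new_map = {}
    if region_name is not None:
        new_map[region_name] = (1, col1 - col0 + 1)
    return GroupAlignment(
        group_id=aln.group_id, names=list(aln.names), rows=new_rows, region_map=new_map
    )


def ungapped_length(row: str) -> int:
    return len(row) - row.count(GAP)


def filter_min_length(aln: GroupAlignment, min_ungapped: int = 475) -> GroupAlignment:
    """Drop rows whose ungapped length is below ``min_ungapped``.

    The default of 475 bp reflects the usual minimum for a usable V4-V5
    fragment. Survivor order is preserved; the number removed is logged.
    An empty result is allowed.
    """
    keep = [
        (n, r) for n, r in zip(aln.names, aln.rows) if ungapped_length(r) >= min_ungapped
    ]
    removed = aln.n_seq - len(keep)
    if removed:
        logger.info(
            "group %s: removed %d/%d sequences shorter than %d ungapped bp",
            aln.group_id, removed, aln.n_seq, min_ungapped,
        )
    return replace(
        aln,
        names=[n for n, _ in keep],
        rows=[r for _, r in keep],
        region_map=dict(aln.region_map),
    )


def read_region_table(path: str | Path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read a TSV of (group_id, region_name, start, end) into nested dicts."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "group_id":  # header
                continue
            if len(parts) != 4:
                raise InputError(f"{path}:{line_no}: expected 4 tab-separated fields")
            gid, rname, start, end = parts
            out.setdefault(gid, {})[rname] = (int(start), int(end))
    return out


def write_region_table(
    regions: dict[str, dict[str, tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tregion_name\tstart\tend\n")
        for gid, rmap in regions.items():
            for rname, (start, end) in rmap.items():
                fh.write(f"{gid}\t{rname}\t{start}\t{end}\n")
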