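"""Sequence and alignment I/O: FASTA, FASTQ, and PAF.

All coordinates are 0-based, half-open, matching PAF's native convention.
For minus-strand alignments the query interval refers to the original
(forward) query sequence while the target interval is always forward.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO as _BioSeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_IUPAC_AMBIG = re.compile(r"[RYSWKMBDHV]")
_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Internally inconsistent record (e.g. CIGAR vs. interval lengths)."""


@dataclass(frozen=True)
class ReadRecord:
    """One read or contig: an id, a DNA sequence and optional qualities."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(
            self.id,
            self.sequence.translate(COMPLEMENT)[::-1],
            self.quality[::-1] if self.quality is not None else None,
        )


@dataclass
class AlignmentBlock:
    """One aligned segment of a query on a target.

    Tallies follow the half-open interval arithmetic::

        matches + mismatches + del_bases == tend - tstart
        matches + mismatches + ins_bases == qend - qstart
        columns == matches + mismatches + ins_bases + del_bases

    ``lossy`` is set when the source PAF line carried neither a cg:Z CIGAR
    nor an NM:i tag, so mismatches could not be separated from indels.
    """

    query_id: str
    query_len: int
    qstart: int
    qend: int
    strand: str
    target_id: str
    target_len: int
    tstart: int
    tend: int
    matches: int
    mismatches: int = 0
    ins_bases: int = 0
    del_bases: int = 0
    ins_events: int = 0
    del_events: int = 0
    lossy: bool = False

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.ins_bases + self.del_bases

    @property
    def identity(self) -> float:
        """Percent identity: 100 * matches / alignment columns."""
        return 100.0 * self.matches / self.columns

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart

    def validate(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.query_len):
            raise ValidationError(
                f"{self.query_id}: bad query interval "
                f"[{self.qstart},{self.qend}) for length {self.query_len}"
            )
        if not (0 <= self.tstart < self.tend <= self.target_len):
            raise ValidationError(
                f"{self.query_id}->{self.target_id}: bad target interval "
                f"[{self.tstart},{self.tend}) for length {self.target_len}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"{self.query_id}: bad strand {self.strand!r}")
        if self.matches + self.mismatches + self.del_bases != self.target_span:
            raise ValidationError(
                f"{self.query_id}->{self.target_id}: tallies inconsistent with "
                f"target span {self.target_span}"
            )
        if self.matches + self.mismatches + self.ins_bases != self.query_span:
            raise ValidationError(
                f"{self.query_id}->{self.target_id}: tallies inconsistent with "
                f"query span {self.query_span}"
            )


def _open_text(path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_sequence(seq: str, where: str) -> str:
    seq = seq.upper().replace("U", "T")
    if _IUPAC_AMBIG.search(seq):
        logger.warning("%s: ambiguity codes replaced by N", where)
        seq = _IUPAC_AMBIG.sub("N", seq)
    return seq


def read_fasta(path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTA file into ReadRecords.

    Sequences are uppercased, U is mapped to T and ambiguity codes other
    than N are replaced by N. Empty sequences are a parse error.
    """
    records: list[ReadRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for i, rec in enumerate(_BioSeqIO.parse(handle, "fasta"), start=1):
            seq = str(rec.seq)
            if not seq:
                raise ParseError(f"{path}: record #{i} ({rec.id!r}): empty sequence")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate id {rec.id!r} (record #{i})")
            seen.add(rec.id)
            records.append(ReadRecord(rec.id, _clean_sequence(seq, f"{path}:{rec.id}")))
    if not records:
        with _open_text(path) as handle:
            if handle.read(1) not in ("", ">"):
                raise ParseError(f"{path}: not a FASTA file (no '>' header)")
    return records


def read_fastq(path) -> list[ReadRecord]:
    """Read a 4-line-per-record FASTQ file; qualities preserved verbatim."""
    records: list[ReadRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        try:
            for i, (title, seq, qual) in enumerate(
                FastqGeneralIterator(handle), start=1
            ):
                rid = title.split()[0]
                if not seq:
                    raise ParseError(f"{path}: record #{i} ({rid!r}): empty sequence")
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record #{i} ({rid!r}): sequence/quality "
                        f"length mismatch ({len(seq)} vs {len(qual)})"
                    )
                if rid in seen:
                    raise ParseError(f"{path}: duplicate id {rid!r} (record #{i})")
                seen.add(rid)
                records.append(
                    ReadRecord(rid, _clean_sequence(seq, f"{path}:{rid}"), qual)
                )
        except ValueError as exc:  # Biopython's own 4-line structure errors
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ReadRecord], path, width: int = 80) -> None:
    """Write FASTA, wrapping sequence lines at ``width`` columns."""
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs."""
    ops = _CIGAR_OP.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ParseError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def tallies_from_cigar(cigar: str) -> dict[str, int]:
    """Match/mismatch/indel tallies from an extended (=/X) or M CIGAR.

    'M' ops are counted as matches (mismatches unknown without =/X).
    """
    t = dict.fromkeys(
        ("matches", "mismatches", "ins_bases", "del_bases", "ins_events", "del_events"),
        0,
    )
    extended = False
    for n, op in parse_cigar(cigar):
        if op == "=":
            t["matches"] += n
            extended = True
        elif op == "X":
            t["mismatches"] += n
            extended = True
        elif op == "M":
            t["matches"] += n
        elif op == "I":
            t["ins_bases"] += n
            t["ins_events"] += 1
        elif op in "DN":
            t["del_bases"] += n
            t["del_events"] += 1
        elif op in "SHP":
            continue
    t["extended"] = extended
    return t


def _parse_paf_line(line: str, lineno: int, source: str) -> AlignmentBlock:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(
            f"{source}:{lineno}: PAF line has {len(fields)} columns, expected >= 12"
        )
    try:
        (qid, qlen, qs, qe, strand, tid, tlen, ts, te, nmatch, blocklen) = (
            fields[0],
            int(fields[1]),
            int(fields[2]),
            int(fields[3]),
            fields[4],
            fields[5],
            int(fields[6]),
            int(fields[7]),
            int(fields[8]),
            int(fields[9]),
            int(fields[10]),
        )
    except ValueError as exc:
        raise ParseError(f"{source}:{lineno}: non-integer coordinate: {exc}") from exc

    tags: dict[str, str] = {}
    for tag in fields[12:]:
        parts = tag.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]

    cigar = tags.get("cg")
    nm = tags.get("NM")
    if cigar is not None:
        t = tallies_from_cigar(cigar)
        if not t.pop("extended"):
            # M-only CIGAR: matches column (10) still separates mismatches
            aligned = t["matches"]
            t["matches"] = min(nmatch, aligned)
            t["mismatches"] = aligned - t["matches"]
        block = AlignmentBlock(
            qid, qlen, qs, qe, strand, tid, tlen, ts, te,
            t["matches"], t["mismatches"], t["ins_bases"], t["del_bases"],
            t["ins_events"], t["del_events"],
        )
        try:
            block.validate()
        except ValidationError as exc:
            raise ValidationError(f"{source}:{lineno}: CIGAR inconsistent: {exc}") from exc
        return block
    if nm is not None:
        # NM = mismatches + inserted + deleted bases; split indels using the
        # interval arithmetic: qspan - tspan fixes ins - del.
        qspan, tspan = qe - qs, te - ts
        edit = int(nm)
        ins = max(qspan - tspan, 0)
        dele = max(tspan - qspan, 0)
        mism = edit - ins - dele
        if mism < 0:
            raise ValidationError(
                f"{source}:{lineno}: NM:i:{edit} smaller than interval length "
                f"difference |{qspan}-{tspan}|"
            )
        block = AlignmentBlock(
            qid, qlen, qs, qe, strand, tid, tlen, ts, te,
            qspan - mism - ins, mism, ins, dele,
            int(ins > 0), int(dele > 0),
        )
        block.validate()
        return block
    # Lossy mode: only the mandatory columns. matches = residue matches
    # (col 10); the remainder of the block length is undifferentiated gap.
    qspan, tspan = qe - qs, te - ts
    matches = min(nmatch, qspan, tspan)
    block = AlignmentBlock(
        qid, qlen, qs, qe, strand, tid, tlen, ts, te,
        matches, 0,
        qspan - matches, tspan - matches,
        int(qspan > matches), int(tspan > matches),
        lossy=True,
    )
    block.validate()
    return block


def read_paf(path) -> list[AlignmentBlock]:
    """Read a PAF file (12 mandatory columns, optional NM:i / cg:Z tags)."""
    blocks = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            blocks.append(_parse_paf_line(line, lineno, str(path)))
    return blocks


def paf_line(block: AlignmentBlock, mapq: int = 60) -> str:
    """Render a block as one PAF line with NM:i and cg:Z-free exact tallies.

    The CIGAR written is a canonical (not positionally faithful) extended
    CIGAR encoding the tallies: runs of =, X, I, D sized to the counts.
    It satisfies the interval arithmetic and round-trips through read_paf.
    """
    parts = []
    mism, ins, dele = block.mismatches, block.ins_bases, block.del_bases
    ins_ev = max(block.ins_events, 1 if ins else 0)
    del_ev = max(block.del_events, 1 if dele else 0)
    if block.matches:
        parts.append(f"{block.matches}=")
    if mism:
        parts.append(f"{mism}X")
    # spread indel bases over the recorded event counts
    for total, ev, op in ((ins, ins_ev, "I"), (dele, del_ev, "D")):
        if total:
            base, extra = divmod(total, ev)
            for i in range(ev):
                parts.append(f"{base + (1 if i < extra else 0)}{op}")
    cigar = "".join(parts)
    nm = mism + ins + dele
    return "\t".join(
        str(x)
        for x in (
            block.query_id, block.query_len, block.qstart, block.qend,
            block.strand, block.target_id, block.target_len, block.tstart,
            block.tend, block.matches, block.columns, mapq,
            f"NM:i:{nm}", f"cg:Z:{cigar}",
        )
    )


def write_paf(blocks: Iterable[AlignmentBlock], path) -> None:
    with _open_text(path, "wt") as out:
        for block in blocks:
            out.write(paf_line(block) + "\n")
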