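"""Readers and writers for the external formats the toolkit touches.

Coordinate convention: every interval held in memory is 0-based, half-open.
Writers convert at the boundary — GFF3 and RepeatMasker ``.out``/``.align``
are 1-based closed, BED is 0-based half-open.  Sequences are stored
uppercase; nucleotide input may use U (mapped to T).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One sequence (consensus, genome contig, or protein) with its header."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seqid}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def to_one_based(self) -> tuple[int, int]:
        """(start, end) in 1-based closed coordinates."""
        return self.start + 1, self.end

    @classmethod
    def from_one_based(
        cls, seqid: str, start: int, end: int, strand: str = ".", label: str = ""
    ) -> "GenomicInterval":
        return cls(seqid, start - 1, end, strand, label)


@dataclass(frozen=True)
class RepeatHit:
    """One RepeatMasker annotation row: a genomic TE copy."""

    interval: GenomicInterval
    family: str
    class_label: str = ""
    smith_waterman_score: float = 0.0
    percent_divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("RepeatHit family must be nonempty")
        if not 0.0 <= self.percent_divergence <= 100.0:
            raise ValueError(
                f"percent_divergence {self.percent_divergence} out of [0, 100]"
            )


@dataclass(frozen=True)
class DomainHitRow:
    """One row of an hmmsearch-style domain hit table."""

    query_id: str
    profile_name: str
    bit_score: float
    e_value: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.ali_start < 0 or self.ali_start >= self.ali_end:
            raise ValueError(
                f"invalid alignment coordinates {self.ali_start}..{self.ali_end}"
            )
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, nucleotide: bool = True
) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, in file order.

    Sequences are uppercased; in nucleotide mode U is mapped to T.
    Duplicate ids are a hard error.  An empty file yields an empty list
    with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .align
# ---------------------------------------------------------------------------

# Header of an alignment block, e.g.
#   1234 8.25 0.00 0.00 chr1 1001 2000 (98000) C fam1#DNA/hAT 1 1000 (0) m_b1 1
_ALIGN_HEADER_RE = re.compile(r"^\d+\s+[\d.]+\s+[\d.]+\s+[\d.]+\s+\S+\s+\d+")

# An aligned sequence row: "  name  start  SEQ  end" (optional leading C for
# reverse-strand query rows in real RepeatMasker output).
_ALIGN_SEQ_RE = re.compile(
    r"^\s*(?:C\s+)?(\S+)\s+(\d+)\s+([A-Za-z\-]+)\s+(\d+)\s*$"
)

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def count_substitutions(
    query_row: str, cons_row: str, exclude_cpg: bool = False
) -> tuple[int, int, int, int]:
    """Count (aligned_sites, transitions, transversions, other) between two
    aligned rows.

    Gap columns and columns containing N (or any non-ACGT symbol) are
    excluded.  ``exclude_cpg`` additionally drops columns where the consensus
    has a CpG dinucleotide, mirroring the option of RepeatMasker's
    calcDivergence.
    """
    if len(query_row) != len(cons_row):
        raise ValueError("aligned rows differ in length")
    q = query_row.upper()
    c = cons_row.upper()
    cpg_cols: set[int] = set()
    if exclude_cpg:
        # CpG on the consensus, skipping gap columns
        prev_idx = None
        for i, base in enumerate(c):
            if base == "-":
                continue
            if prev_idx is not None and c[prev_idx] == "C" and base == "G":
                cpg_cols.update((prev_idx, i))
            prev_idx = i
    sites = ts = tv = other = 0
    for i, (a, b) in enumerate(zip(q, c)):
        if a not in "ACGT" or b not in "ACGT" or i in cpg_cols:
            continue
        sites += 1
        if a == b:
            continue
        if (a, b) in _TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    return sites, ts, tv, other


def parse_rm_align(
    path: str | Path, exclude_cpg: bool = False
) -> list["CopyAlignment"]:
    """Parse a RepeatMasker ``.align`` file into per-copy substitution counts.

    One record per alignment block.  Within a block the first sequence name
    encountered is the genomic query; the other name is the consensus.
    Truncated blocks (no aligned rows, or rows of mismatched length) are
    skipped with a warning; the number of skips is logged at the end.
    """
    text = Path(path).read_text()
    records: list[CopyAlignment] = []
    skipped = 0

    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if _ALIGN_HEADER_RE.match(line):
            if current is not None:
                blocks.append(current)
            current = [line]
        elif current is not None:
            current.append(line)
    if current is not None:
        blocks.append(current)

    for block in blocks:
        rec = _parse_align_block(block, exclude_cpg=exclude_cpg)
        if rec is None:
            skipped += 1
        else:
            records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d truncated alignment block(s)", path, skipped)
    return records


@dataclass(frozen=True)
class CopyAlignment:
    """Substitution counts for one genomic copy aligned to its consensus."""

    copy_interval: GenomicInterval
    family: str
    aligned_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.aligned_sites:
            raise ValueError("substitutions exceed aligned sites")
        if min(self.aligned_sites, self.transitions, self.transversions) < 0:
            raise ValueError("counts must be >= 0")


def _parse_align_block(
    lines: list[str], exclude_cpg: bool
) -> CopyAlignment | None:
    header = lines[0].split()
    try:
        seqid = header[4]
        qstart = int(header[5])
        qend = int(header[6])
        # family field follows "(left)"; may be preceded by orientation C
        idx = 8
        strand = "+"
        if header[idx] == "C" or header[idx] == "+":
            strand = "-" if header[idx] == "C" else "+"
            idx += 1
        family = header[idx].split("#")[0]
    except (IndexError, ValueError):
        logger.warning("unparseable .align header: %s", lines[0])
        return None

    query_rows: list[str] = []
    cons_rows: list[str] = []
    query_name: str | None = None
    for line in lines[1:]:
        if line.startswith(("Matrix", "Transitions", "Gap_init", "Kimura")):
            continue
        m = _ALIGN_SEQ_RE.match(line)
        if not m:
            continue
        name, _, seq, _ = m.groups()
        # guard against annotation midlines that happen to match
        if set(seq.upper()) - set("ACGTNRYKMSWBDHV-"):
            continue
        if query_name is None:
            query_name = name
        if name == query_name:
            query_rows.append(seq)
        else:
            cons_rows.append(seq)

    qrow = "".join(query_rows)
    crow = "".join(cons_rows)
    if not qrow or not crow or len(qrow) != len(crow):
        return None
    sites, ts, tv, _ = count_substitutions(qrow, crow, exclude_cpg=exclude_cpg)
    if sites == 0:
        return None
    try:
        interval = GenomicInterval.from_one_based(seqid, qstart, qend, strand, family)
    except ValueError:
        return None
    return CopyAlignment(interval, family, sites, ts, tv)


def write_rm_align(
    path: str | Path,
    blocks: Sequence[tuple[GenomicInterval, str, str, str]],
    genome_sizes: dict[str, int] | None = None,
    width: int = 50,
) -> None:
    """Write alignment blocks in the RepeatMasker ``.align`` dialect.

    ``blocks`` holds (copy interval, family, query aligned row, consensus
    aligned row) tuples.
    """
    with open(path, "w") as fh:
        for n, (iv, family, qrow, crow) in enumerate(blocks):
            sites, ts, tv, _ = count_substitutions(qrow, crow)
            div = 100.0 * (ts + tv) / sites if sites else 0.0
            start1, end1 = iv.to_one_based()
            left = (genome_sizes or {}).get(iv.seqid, end1) - end1
            fh.write(
                f"{sites} {div:.2f} 0.00 0.00 {iv.seqid} {start1} {end1} "
                f"({left}) {family}#Unknown 1 {len(crow.replace('-', ''))} (0) "
                f"m_b1s001i{n} {n}\n\n"
            )
            qpos, cpos = start1, 1
            for i in range(0, len(qrow), width):
                qchunk = qrow[i : i + width]
                cchunk = crow[i : i + width]
                qlen = len(qchunk.replace("-", ""))
                clen = len(cchunk.replace("-", ""))
                fh.write(f"  {iv.seqid:<15} {qpos} {qchunk} {qpos + qlen - 1}\n")
                fh.write(f"  {family:<15} {cpos} {cchunk} {cpos + clen - 1}\n\n")
                qpos += qlen
                cpos += clen
            fh.write(f"Transitions / transversions = {ts} / {tv}\n")
            fh.write("Gap_init rate = 0.00, avg. gap size = 0.00\n\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def parse_rm_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` annotation table (1-based closed)."""
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 11 or not fields[0].replace(".", "").isdigit():
                continue  # header / blank lines
            score = float(fields[0])
            div = float(fields[1])
            seqid = fields[4]
            start = int(fields[5])
            end = int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            family = fields[9]
            class_label = fields[10]
            hits.append(
                RepeatHit(
                    GenomicInterval.from_one_based(seqid, start, end, strand),
                    family=family,
                    class_label=class_label,
                    smith_waterman_score=score,
                    percent_divergence=div,
                )
            )
    return hits


def write_rm_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query   "
            "matching repeat\n\n"
        )
        for h in hits:
            s1, e1 = h.interval.to_one_based()
            strand = "+" if h.interval.strand != "-" else "C"
            fh.write(
                f"{h.smith_waterman_score:7.0f} {h.percent_divergence:5.1f}"
                f"  0.0  0.0  {h.interval.seqid} {s1} {e1} (0) {strand} "
                f"{h.family} {h.class_label or 'Unknown'} 1 {len(h.interval)} (0) 1\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def parse_gff3_transcripts(
    path: str | Path,
    feature_types: Sequence[str] = ("mRNA", "transcript"),
) -> list[GenomicInterval]:
    """Extract transcript intervals from a GFF3 file.

    1-based closed input coordinates become 0-based half-open.  Records with
    end < start are rejected and logged.  The interval label is the ID
    attribute when present, else ``seqid:start-end``.
    """
    wanted = set(feature_types)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            seqid, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            if ftype not in wanted:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError:
                logger.warning("%s line %d: non-numeric coordinates", path, lineno)
                continue
            if e < s:
                logger.warning("%s line %d: end < start, rejected", path, lineno)
                continue
            label = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    label = kv[3:]
                    break
            if not label:
                label = f"{seqid}:{s}-{e}"
            intervals.append(
                GenomicInterval.from_one_based(
                    seqid, s, e, strand if strand in "+-" else ".", label
                )
            )
    return intervals


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3-6 columns, 0-based half-open)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            seqid, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(seqid, start, end, strand, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.seqid}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t"
                f"{iv.strand if iv.strand != '.' else '+'}\n"
            )


# ---------------------------------------------------------------------------
# hmmsearch-style domain tables
# ---------------------------------------------------------------------------

def parse_domain_table(path: str | Path) -> list[DomainHitRow]:
    """Parse an hmmsearch-style whitespace-delimited domain table.

    Two dialects are accepted: the full 23-column ``--domtblout`` layout
    (query = target name, profile = query name, score = domain bit score,
    e-value = i-Evalue, coordinates = ali from/to) and a minimal 6-column
    form (query, profile, bit score, e-value, ali start, ali end).  Comment
    lines start with '#'; malformed lines are rejected with their line
    number logged.
    """
    rows: list[DomainHitRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 23:
                    row = DomainHitRow(
                        query_id=fields[0],
                        profile_name=fields[3],
                        bit_score=float(fields[13]),
                        e_value=float(fields[12]),
                        ali_start=int(fields[17]),
                        ali_end=int(fields[18]),
                    )
                elif len(fields) >= 6:
                    row = DomainHitRow(
                        query_id=fields[0],
                        profile_name=fields[1],
                        bit_score=float(fields[2]),
                        e_value=float(fields[3]),
                        ali_start=int(fields[4]),
                        ali_end=int(fields[5]),
                    )
                else:
                    raise ValueError("too few fields")
            except ValueError as exc:
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
                continue
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Stockholm writer, Newick reader
# ---------------------------------------------------------------------------

def write_stockholm(
    alignment: Sequence[tuple[str, str]], path: str | Path
) -> None:
    """Write a (name, aligned sequence) list as minimal Stockholm 1.0."""
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        name_w = max(len(n) for n, _ in alignment)
        for name, seq in alignment:
            fh.write(f"{name:<{name_w}}  {seq}\n")
        fh.write("//\n")


def read_newick(path: str | Path):
    """Read a Newick tree (dendropy.Tree)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
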