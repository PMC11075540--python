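"""ORF extraction and position-specific scoring profiles for TE domains.

The curation pipeline needs to know whether a consensus sequence carries a
transposition domain (reverse transcriptase, transposase, tyrosine
recombinase, ...).  Domains are modelled as ungapped log-odds profiles
(PSSMs) built from curated amino-acid alignments and scanned against the
six-frame ORFs of each consensus.  Precomputed hmmsearch tables can be
ingested instead via :func:`hits_from_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from tecurate.seqio import DomainHitRow, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

DEFAULT_MIN_AA = 200          # getorf-style minimum ORF size
DEFAULT_BITS_PER_COLUMN = 0.5  # hit threshold, in bits per scored column


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-to-stop ORF on one of the six frames of a nucleotide record.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand of
    the source sequence, regardless of frame sign.
    """

    source_id: str
    frame: int  # in {-3, -2, -1, +1, +2, +3}
    aa_seq: str
    nt_start: int
    nt_end: int

    def __post_init__(self) -> None:
        if self.frame not in {-3, -2, -1, 1, 2, 3}:
            raise ValueError(f"invalid frame {self.frame}")
        if "*" in self.aa_seq:
            raise ValueError("ORF contains an internal stop")

    def __len__(self) -> int:
        return len(self.aa_seq)


def extract_orfs(
    record: SequenceRecord, min_aa: int = DEFAULT_MIN_AA
) -> list[OpenReadingFrame]:
    """All maximal stop-to-stop ORFs of >= ``min_aa`` residues on 6 frames.

    ORFs are delimited by stop codons (or sequence ends), not by ATG,
    matching getorf's default behaviour.  Records shorter than 3*min_aa
    cannot contain a qualifying ORF and yield an empty list.
    """
    n = len(record.seq)
    if n < 3 * min_aa:
        return []
    orfs: list[OpenReadingFrame] = []
    for strand, seq in ((1, record.seq), (-1, revcomp(record.seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            usable = (n - offset) // 3 * 3
            if usable < 3:
                continue
            aa = str(Seq(seq[offset : offset + usable]).translate())
            start_aa = 0
            for segment in aa.split("*"):
                if len(segment) >= min_aa:
                    # aa coords -> nt coords on the scanned strand
                    s_nt = offset + 3 * start_aa
                    e_nt = s_nt + 3 * len(segment)
                    if strand == -1:
                        s_nt, e_nt = n - e_nt, n - s_nt
                    orfs.append(
                        OpenReadingFrame(record.id, frame, segment, s_nt, e_nt)
                    )
                start_aa += len(segment) + 1
    return orfs


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainProfile:
    """Ungapped per-position log-odds profile over the 20 amino acids.

    ``columns`` has shape (length, 20) in bits, ordered by
    :data:`AA_ALPHABET`.  ``te_order``/``te_superfamily`` carry the taxonomy
    that a hit against this profile implies.
    """

    name: str
    te_order: str
    te_superfamily: str
    columns: np.ndarray
    pseudocount_mass: float = 1.0
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must have shape (L, 20)")
        if self.columns.shape[0] < 10:
            raise ValueError("profile must have length >= 10")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-scoring residue at each column."""
        return "".join(AA_ALPHABET[i] for i in np.argmax(self.columns, axis=1))


def build_profile(
    alignment: Sequence[str],
    name: str,
    te_order: str,
    te_superfamily: str = "",
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
    max_gap_frac: float = 0.5,
) -> DomainProfile:
    """Build a log-odds profile from aligned amino-acid strings.

    Columns with more than ``max_gap_frac`` gaps are dropped (match-column
    rule).  Per column the score of residue a is

        log2( (count_a + pseudocount * bg_a) / (total + pseudocount) / bg_a )

    with a uniform background by default.  Deterministic for fixed input and
    invariant to the order of the training sequences.
    """
    if len(alignment) < 2:
        raise ValueError("at least 2 aligned sequences required")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("aligned sequences must have equal length")
    if background is None:
        bg = np.full(20, 1.0 / 20)
    else:
        bg = np.asarray(background, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background distribution must sum to 1")

    rows = [s.upper().replace(".", "-") for s in alignment]
    n_seq = len(rows)
    match_cols = [
        j for j in range(L)
        if sum(r[j] == "-" for r in rows) / n_seq <= max_gap_frac
    ]
    if not match_cols:
        raise ValueError("alignment has no match columns (all-gap?)")

    columns = np.zeros((len(match_cols), 20))
    for out_j, j in enumerate(match_cols):
        counts = np.zeros(20)
        for r in rows:
            idx = _AA_INDEX.get(r[j])
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        probs = (counts + pseudocount * bg) / (total + pseudocount)
        columns[out_j] = np.log2(probs / bg)
    return DomainProfile(
        name, te_order, te_superfamily, columns, pseudocount_mass=pseudocount,
        background=bg,
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileHit:
    """Best-scoring window of an ORF against a domain profile (bits)."""

    query_id: str
    profile: str
    score: float
    start: int
    end: int
    mapped_order: str
    mapped_superfamily: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("hit score must be finite")
        if self.start >= self.end:
            raise ValueError("hit start must precede end")

    @property
    def span(self) -> int:
        return self.end - self.start


def _encode_aa(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown symbols get -1 (score 0)."""
    return np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=np.int64)


def scan_profile(
    orf: OpenReadingFrame,
    profile: DomainProfile,
    bits_per_column: float = DEFAULT_BITS_PER_COLUMN,
) -> list[ProfileHit]:
    """Ungapped sliding-window scan of an ORF against a profile.

    Returns at most one hit: the best-scoring window, reported when its
    total score reaches ``bits_per_column * scored_columns``.  For ORFs
    shorter than the profile the ORF is slid along the profile instead and
    the best partial-window score is subjected to the same per-column
    threshold.  Residues outside the 20-letter alphabet contribute 0.
    """
    idx = _encode_aa(orf.aa_seq)
    L, W = profile.length, len(idx)
    cols = profile.columns
    best_score = -np.inf
    best_start = 0
    ncols = min(L, W)
    if W >= L:
        # profile slides along the ORF
        valid = idx >= 0
        safe_idx = np.where(valid, idx, 0)
        for s in range(W - L + 1):
            window = safe_idx[s : s + L]
            scores = cols[np.arange(L), window]
            total = float(np.sum(scores * valid[s : s + L]))
            if total > best_score:
                best_score, best_start = total, s
        hit_start, hit_end = best_start, best_start + L
    else:
        # ORF slides along the profile; score the full ORF against each
        # contiguous stretch of profile columns
        valid = idx >= 0
        safe_idx = np.where(valid, idx, 0)
        for s in range(L - W + 1):
            scores = cols[np.arange(s, s + W), safe_idx]
            total = float(np.sum(scores * valid))
            if total > best_score:
                best_score, best_start = total, s
        hit_start, hit_end = 0, W
    threshold = bits_per_column * ncols
    if best_score < threshold:
        return []
    return [
        ProfileHit(
            query_id=orf.source_id,
            profile=profile.name,
            score=best_score,
            start=hit_start,
            end=hit_end,
            mapped_order=profile.te_order,
            mapped_superfamily=profile.te_superfamily,
        )
    ]


def scan_all(
    orfs: Iterable[OpenReadingFrame],
    profiles: Iterable[DomainProfile],
    bits_per_column: float = DEFAULT_BITS_PER_COLUMN,
) -> list[ProfileHit]:
    """Scan every ORF against every profile, keeping per ORFxprofile bests."""
    profiles = list(profiles)
    hits: list[ProfileHit] = []
    for orf in orfs:
        for prof in profiles:
            hits.extend(scan_profile(orf, prof, bits_per_column))
    return hits


def select_best_hits(
    hits: Iterable[ProfileHit],
) -> dict[str, ProfileHit]:
    """Per query, the single winning hit.

    Order of preference: highest score, then longest aligned span, then
    lexicographically smallest profile name.  The full hit list stays with
    the caller for the classifier's ambiguity check.
    """
    best: dict[str, ProfileHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key = (-hit.score, -hit.span, hit.profile)
        cur_key = (-cur.score, -cur.span, cur.profile)
        if key < cur_key:
            best[hit.query_id] = hit
    return best


def hits_from_table(
    rows: Iterable[DomainHitRow],
    taxonomy: Mapping[str, tuple[str, str]],
) -> list[ProfileHit]:
    """Convert external hmmsearch-style rows into ProfileHits.

    ``taxonomy`` maps profile name -> (te_order, te_superfamily); unmapped
    profiles are kept with order "unknown".
    """
    hits = []
    for row in rows:
        order, superfam = taxonomy.get(row.profile_name, ("unknown", ""))
        hits.append(
            ProfileHit(
                query_id=row.query_id,
                profile=row.profile_name,
                score=row.bit_score,
                start=row.ali_start,
                end=row.ali_end,
                mapped_order=order,
                mapped_superfamily=superfam,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_profile(profile: DomainProfile, path: str | Path) -> None:
    """Serialize a profile as TSV with a '#'-prefixed header block."""
    with open(path, "w") as fh:
        fh.write(f"# name\t{profile.name}\n")
        fh.write(f"# te_order\t{profile.te_order}\n")
        fh.write(f"# te_superfamily\t{profile.te_superfamily}\n")
        fh.write(f"# length\t{profile.length}\n")
        fh.write(f"# pseudocount\t{profile.pseudocount_mass}\n")
        fh.write("pos\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, col in enumerate(profile.columns):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in col) + "\n")


def read_profile(path: str | Path) -> DomainProfile:
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value.strip()
            elif line.startswith("pos\t") or not line.strip():
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    return DomainProfile(
        name=meta["name"],
        te_order=meta["te_order"],
        te_superfamily=meta.get("te_superfamily", ""),
        columns=np.array(rows),
        pseudocount_mass=float(meta.get("pseudocount", 1.0)),
    )
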