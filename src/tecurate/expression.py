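"""Expression normalization, upstream TE-gene pairing, and coexpression.

TEs inserted within 1,000 nt upstream of a transcription start can sit in
the promoter's regulatory neighbourhood.  This module pairs TE annotations
with downstream genes through that strand-aware window, normalizes count
matrices to TPM, computes Pearson coexpression of log-transformed
abundances per pair, summarizes differential-expression tables under the
inclusive padj <= alpha rule, and runs Welch t-tests of each condition
against a reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tecurate.seqio import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_WINDOW = 1_000
DEFAULT_DE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Expression matrix + TPM
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with optional feature lengths (bp)."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    feature_lengths: Optional[pd.Series] = None  # bp, for TPM
    unit: str = "counts"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.values.index)

    @classmethod
    def from_tsv(cls, path, length_column: str = "length") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = None
        if length_column in df.columns:
            lengths = df.pop(length_column)
        return cls(df, lengths)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> transcripts per million.

    Per sample: rate_i = count_i / (length_i / 1000); TPM_i = rate_i /
    sum(rates) * 1e6.  Every sample column with any signal sums to 1e6;
    all-zero samples stay all-zero (logged).
    """
    if matrix.feature_lengths is None:
        raise ValueError("feature lengths required for TPM")
    lengths_kb = matrix.feature_lengths.to_numpy(dtype=float) / 1_000.0
    if (lengths_kb <= 0).any():
        raise ValueError("feature lengths must be positive")
    rates = matrix.values.to_numpy(dtype=float) / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning("%d all-zero sample(s) left at zero", int(zero_cols.sum()))
    totals[zero_cols] = 1.0  # avoid 0/0; columns stay zero
    tpm = rates / totals * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=matrix.values.index, columns=matrix.values.columns),
        matrix.feature_lengths,
        unit="TPM",
    )


# ---------------------------------------------------------------------------
# Upstream pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpstreamPair:
    """A TE located within the upstream window of a transcript start."""

    gene_id: str
    te_id: str
    distance: int  # nt between TE nearest edge and the transcript start
    te_interval: GenomicInterval
    gene_interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def find_upstream_pairs(
    genes: Sequence[GenomicInterval],
    tes: Sequence[GenomicInterval],
    window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[UpstreamPair]:
    """All TE-gene pairs with the TE within ``window`` nt upstream.

    For a + strand gene the TE's end must lie in [start - window, start];
    for a - strand gene the TE's start must lie in [end, end + window].
    The distance is the gap between the TE's nearest edge and the
    transcript start; a TE abutting or overlapping the start counts with
    distance 0.  Many-to-many: a TE may pair with several genes.
    """
    tes_by_seq: dict[str, list[GenomicInterval]] = {}
    for te in tes:
        tes_by_seq.setdefault(te.seqid, []).append(te)
    pairs: list[UpstreamPair] = []
    for gene in genes:
        candidates = tes_by_seq.get(gene.seqid, ())
        for te in candidates:
            if gene.strand == "-":
                tss = gene.end  # transcript start at the right edge
                if tss <= te.start <= tss + window:
                    distance = te.start - tss
                elif te.start < tss <= te.end:
                    distance = 0  # TE overlaps the start
                else:
                    continue
            else:
                tss = gene.start
                if tss - window <= te.end <= tss:
                    distance = tss - te.end
                elif te.start <= tss < te.end:
                    distance = 0
                else:
                    continue
            pairs.append(
                UpstreamPair(
                    gene_id=gene.label or f"{gene.seqid}:{gene.start}",
                    te_id=te.label or f"{te.seqid}:{te.start}",
                    distance=distance,
                    te_interval=te,
                    gene_interval=gene,
                )
            )
    return pairs


def pairs_to_frame(pairs: Iterable[UpstreamPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_id, p.te_id, p.distance) for p in pairs],
        columns=["gene_id", "te_id", "distance"],
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in an input


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p-value.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom.  Zero variance in either vector flags the result degenerate
    with r = nan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return CorrelationResult(math.nan, math.nan, n, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def log_transform(tpm: np.ndarray | pd.Series, offset: float = 1.0) -> np.ndarray:
    """Natural-log transform ln(TPM + offset) used for coexpression."""
    return np.log(np.asarray(tpm, dtype=float) + offset)


def coexpression(
    pairs: Sequence[UpstreamPair],
    expression: ExpressionMatrix,
    strata: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Pair-level coexpression of genes and their upstream TEs.

    Mean expression across samples is log-transformed per feature; one
    Pearson correlation is computed per stratum (e.g. compartment) over
    (gene, TE) pairs, or one overall when ``strata`` is None.  ``strata``
    maps gene_id -> stratum label.  Returns a tidy frame with columns
    stratum, r, p_value, n_pairs.
    """
    mean_expr = expression.values.mean(axis=1)
    rows = []
    groups: dict[str, list[UpstreamPair]] = {}
    for p in pairs:
        label = (strata or {}).get(p.gene_id, "all")
        groups.setdefault(label, []).append(p)
    for label, group in sorted(groups.items()):
        usable = [
            p for p in group
            if p.gene_id in mean_expr.index and p.te_id in mean_expr.index
        ]
        if len(usable) < 3:
            logger.warning("stratum %s has < 3 usable pairs, skipped", label)
            continue
        gx = log_transform([mean_expr[p.gene_id] for p in usable])
        tx = log_transform([mean_expr[p.te_id] for p in usable])
        res = pearson(gx, tx)
        rows.append((label, res.r, res.p_value, res.n))
    return pd.DataFrame(rows, columns=["stratum", "r", "p_value", "n_pairs"])


# ---------------------------------------------------------------------------
# Differential-expression summarization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEResultRow:
    """One feature's differential-expression outcome."""

    feature_id: str
    log2_fold_change: float
    padj: Optional[float]  # None = not testable (NA in DESeq2 output)

    def __post_init__(self) -> None:
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"padj {self.padj} outside [0, 1]")


def read_de_table(path) -> list[DEResultRow]:
    """Read a DE result TSV (feature_id, log2_fold_change, padj).

    Rows with padj outside [0, 1] are rejected and logged; empty/NA padj is
    kept as None (not significant).
    """
    df = pd.read_csv(path, sep="\t")
    rows: list[DEResultRow] = []
    for i, rec in df.iterrows():
        padj = rec.get("padj")
        padj = None if pd.isna(padj) else float(padj)
        try:
            rows.append(
                DEResultRow(str(rec.iloc[0]), float(rec["log2_fold_change"]), padj)
            )
        except ValueError as exc:
            logger.warning("DE row %d rejected: %s", i, exc)
    return rows


def summarize_de(
    rows: Iterable[DEResultRow], alpha: float = DEFAULT_DE_ALPHA
) -> dict[str, int]:
    """Partition DE rows into UP / DOWN / NO counts.

    A feature is UP when padj <= alpha (inclusive) and log2FC > 0, DOWN
    when padj <= alpha and log2FC < 0, NO otherwise (including missing
    padj).  Counts always sum to the number of rows.
    """
    counts = {"UP": 0, "DOWN": 0, "NO": 0}
    for row in rows:
        if row.padj is not None and row.padj <= alpha and row.log2_fold_change > 0:
            counts["UP"] += 1
        elif row.padj is not None and row.padj <= alpha and row.log2_fold_change < 0:
            counts["DOWN"] += 1
        else:
            counts["NO"] += 1
    return counts


def summarize_de_by_group(
    rows: Iterable[DEResultRow],
    group_of: dict[str, str],
    alpha: float = DEFAULT_DE_ALPHA,
) -> pd.DataFrame:
    """Per-group (family / superfamily) rollup of UP/DOWN/NO counts."""
    per_group: dict[str, dict[str, int]] = {}
    for row in rows:
        group = group_of.get(row.feature_id, "unknown")
        bucket = per_group.setdefault(group, {"UP": 0, "DOWN": 0, "NO": 0})
        for status, n in summarize_de([row], alpha).items():
            bucket[status] += n
    return (
        pd.DataFrame.from_dict(per_group, orient="index")
        .rename_axis("group")
        .reset_index()
        .sort_values("group", ignore_index=True)
    )


def de_set_comparison(
    per_condition: dict[str, Iterable[DEResultRow]],
    direction: str = "UP",
    alpha: float = DEFAULT_DE_ALPHA,
) -> dict[str, set[str]]:
    """Shared vs condition-unique significant feature sets across conditions.

    Returns {"shared": ids significant in every condition,
    "<condition>_unique": ids significant only there}.
    """
    sig: dict[str, set[str]] = {}
    for cond, rows in per_condition.items():
        chosen = set()
        for row in rows:
            if row.padj is None or row.padj > alpha:
                continue
            if direction == "UP" and row.log2_fold_change > 0:
                chosen.add(row.feature_id)
            elif direction == "DOWN" and row.log2_fold_change < 0:
                chosen.add(row.feature_id)
        sig[cond] = chosen
    out: dict[str, set[str]] = {}
    if sig:
        out["shared"] = set.intersection(*sig.values()) if sig else set()
        for cond, ids in sig.items():
            others = set().union(*(v for c, v in sig.items() if c != cond))
            out[f"{cond}_unique"] = ids - others
    return out


# ---------------------------------------------------------------------------
# Group comparison (condition vs reference)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    condition: str
    t: float
    p_value: float
    direction: str  # "higher", "lower", "equal" relative to reference
    testable: bool
    stars: str = ""


def _stars(p: float) -> str:
    if p <= 0.001:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def group_ttest(
    values_by_condition: dict[str, Sequence[float]],
    reference: str,
    welch: bool = True,
) -> list[GroupTestResult]:
    """Welch t-test of each condition against the reference condition.

    Conditions with fewer than 2 replicates are flagged not-testable.
    Identical groups (zero variance, equal means) report t = 0, p = 1.
    Significance stars: * for p <= 0.05, ** for p <= 0.001.
    """
    if reference not in values_by_condition:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = np.asarray(values_by_condition[reference], dtype=float)
    results: list[GroupTestResult] = []
    for cond, vals in values_by_condition.items():
        if cond == reference:
            continue
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2 or len(ref) < 2:
            results.append(GroupTestResult(cond, math.nan, math.nan, "", False))
            continue
        if np.std(arr) == 0 and np.std(ref) == 0 and np.mean(arr) == np.mean(ref):
            results.append(GroupTestResult(cond, 0.0, 1.0, "equal", True))
            continue
        t, p = stats.ttest_ind(arr, ref, equal_var=not welch)
        direction = "higher" if np.mean(arr) > np.mean(ref) else (
            "lower" if np.mean(arr) < np.mean(ref) else "equal"
        )
        results.append(
            GroupTestResult(cond, float(t), float(p), direction, True, _stars(float(p)))
        )
    return results
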