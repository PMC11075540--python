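"""The curation decision engine.

Combines four strands of evidence into a final taxonomy per consensus:
(1) a coarse order prediction (nonLTR / LTR / DNA) from a naive-Bayes
k-mer model or externally supplied labels, (2) transposition-domain hits
from profile scans or ingested hmmsearch tables, (3) structural evidence
(terminal inverted repeats, size windows), and (4) neighbor-joining
placement against labeled references when domains from different orders
conflict.  Consensus sequences whose best match is an expanded host gene
family (Sel1, BTB, Kelch, kinase, TPR) are masked out; sequences with no
recognizable domain and no MITE structure are relics.

Class II (DNA/TIR) elements are retained only when all four criteria hold:
DNA order prediction, a transposase domain hit, a TIR, and a size between
1 and 17 kb.  TIR-bearing 50 bp - 1 kb sequences lacking a transposase are
MITEs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from tecurate.profiles import ProfileHit, select_best_hits
from tecurate.seqio import SequenceRecord, write_fasta
from tecurate.tirs import (
    DNA_TIR_MAX_BP,
    DNA_TIR_MIN_BP,
    MITE_MAX_BP,
    MITE_MIN_BP,
    TIRFeature,
)

logger = logging.getLogger(__name__)

CLASS_I_ORDERS = {"SINE", "LINE", "LTR", "DIRS", "PLE"}
CLASS_II_ORDERS = {"DNA/TIR", "Crypton", "Maverick", "Helitron", "MITE"}

# coarse 3-way order groups used by the k-mer order predictor
ORDER_TO_COARSE = {
    "SINE": "nonLTR",
    "LINE": "nonLTR",
    "DIRS": "nonLTR",
    "PLE": "nonLTR",
    "LTR": "LTR",
    "DNA/TIR": "DNA",
    "Crypton": "DNA",
    "Maverick": "DNA",
    "Helitron": "DNA",
    "MITE": "DNA",
}

DEFAULT_CONFLICT_MARGIN_BITS = 25.0


def te_class_of(order: str) -> str:
    if order in CLASS_I_ORDERS:
        return "I"
    if order in CLASS_II_ORDERS:
        return "II"
    return "unknown"


# ---------------------------------------------------------------------------
# Order prediction (k-mer naive Bayes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderPrediction:
    consensus_id: str
    label: str  # nonLTR | LTR | DNA | unknown
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of ACGT-only k-mers; ambiguous positions break k-mers."""
    counts = np.zeros(4 ** k)
    code = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    n = len(code)
    if n < k:
        return counts
    valid = code >= 0
    # rolling encoding
    weights = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(code, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    if ok.any():
        ids = (windows[ok] * weights).sum(axis=1)
        np.add.at(counts, ids, 1)
    return counts


@dataclass
class KmerOrderModel:
    """Naive-Bayes k-mer classifier over the coarse TE order groups."""

    k: int = 4
    smoothing: float = 1.0
    classes_: list[str] = field(default_factory=list)
    log_probs_: Optional[np.ndarray] = None  # (n_classes, 4**k)

    @property
    def trained(self) -> bool:
        return self.log_probs_ is not None

    def fit(
        self, records: Sequence[SequenceRecord], labels: Sequence[str]
    ) -> "KmerOrderModel":
        if len(records) != len(labels):
            raise ValueError("records and labels differ in length")
        self.classes_ = sorted(set(labels))
        mats = []
        for cls in self.classes_:
            total = np.zeros(4 ** self.k)
            for rec, lab in zip(records, labels):
                if lab == cls:
                    total += _kmer_counts(rec.seq, self.k)
            probs = (total + self.smoothing) / (total.sum() + self.smoothing * len(total))
            mats.append(np.log(probs))
        self.log_probs_ = np.vstack(mats)
        return self

    def predict(self, record: SequenceRecord) -> OrderPrediction:
        return predict_order_kmer(record, self)


def train_order_model(
    records: Sequence[SequenceRecord],
    labels: Sequence[str],
    k: int = 4,
    smoothing: float = 1.0,
) -> KmerOrderModel:
    return KmerOrderModel(k=k, smoothing=smoothing).fit(records, labels)


def predict_order_kmer(
    record: SequenceRecord, model: KmerOrderModel
) -> OrderPrediction:
    """Highest-posterior coarse order under the k-mer model.

    The posterior is normalized across classes (uniform prior).  Sequences
    with no scorable k-mer (e.g. all Ns) come back "unknown" with uniform
    confidence.
    """
    if not model.trained:
        raise ValueError("order model is untrained")
    counts = _kmer_counts(record.seq, model.k)
    n_classes = len(model.classes_)
    if counts.sum() == 0:
        return OrderPrediction(record.id, "unknown", 1.0 / n_classes)
    scores = model.log_probs_ @ counts
    scores -= scores.max()
    post = np.exp(scores)
    post /= post.sum()
    best = int(np.argmax(post))
    return OrderPrediction(record.id, model.classes_[best], float(post[best]))


# ---------------------------------------------------------------------------
# Expanded-gene masking
# ---------------------------------------------------------------------------

def mask_expanded_genes(
    te_hits: Iterable[ProfileHit],
    expanded_hits: Iterable[ProfileHit],
) -> set[str]:
    """Ids whose best expanded-gene hit beats their best TE-domain hit.

    Expanded host gene families (Sel1, BTB, Kelch, protein kinase, TPR)
    can carry partial TE insertions; a consensus dominated by such a
    profile is a chimeric gene model, not a TE, and is dropped from
    curation.
    """
    best_te = select_best_hits(te_hits)
    best_exp = select_best_hits(expanded_hits)
    masked: set[str] = set()
    for qid, exp_hit in best_exp.items():
        te_hit = best_te.get(qid)
        if te_hit is None or exp_hit.score > te_hit.score:
            masked.add(qid)
    return masked


# ---------------------------------------------------------------------------
# Phylogenetic disambiguation
# ---------------------------------------------------------------------------

def _p_distance(a: str, b: str) -> float:
    """Uncorrected amino-acid p-distance over pairwise-complete sites."""
    n = min(len(a), len(b))
    sites = diffs = 0
    for x, y in zip(a[:n].upper(), b[:n].upper()):
        if x in "-X*" or y in "-X*":
            continue
        sites += 1
        if x != y:
            diffs += 1
    return diffs / sites if sites else 1.0


def resolve_ambiguous(
    consensus_id: str,
    conflicting_hits: Sequence[ProfileHit],
    references: Sequence[tuple[str, str, str]],
    query_seq: str,
    external_tree=None,
) -> tuple[str, str, bool]:
    """Assign an order to a multi-domain consensus by tree placement.

    ``references`` holds (name, order, amino-acid sequence) for labeled
    exemplars of each candidate order; ``query_seq`` is the consensus'
    domain-region protein.  A neighbor-joining tree is built from pairwise
    p-distances and the query takes the label of the group with the
    smallest mean path (patristic) distance.  An externally supplied
    Newick tree (dendropy.Tree, taxa named like the references plus the
    query) overrides the built-in NJ.  Returns (order, superfamily,
    phylo_resolved); with fewer than 3 taxa or an exact tie the best-score
    hit's label is returned with phylo_resolved False.
    """
    best = max(conflicting_hits, key=lambda h: h.score)
    fallback = (best.mapped_order, best.mapped_superfamily, False)
    if external_tree is not None:
        mean_dist = _tree_mean_distances(external_tree, consensus_id, references)
    else:
        if len(references) + 1 < 3:
            return fallback
        names = [consensus_id] + [name for name, _, _ in references]
        seqs = [query_seq] + [seq for _, _, seq in references]
        n = len(names)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = _p_distance(seqs[i], seqs[j])
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(dm, ids=names))
        tip_dm = tree.tip_tip_distances()
        order_of = {name: order for name, order, _ in references}
        dists: dict[str, list[float]] = {}
        for name, order in order_of.items():
            dists.setdefault(order, []).append(tip_dm[consensus_id, name])
        mean_dist = {order: float(np.mean(v)) for order, v in dists.items()}
    if not mean_dist:
        return fallback
    ranked = sorted(mean_dist.items(), key=lambda kv: kv[1])
    if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
        return fallback  # equidistant: fall back to best score
    order = ranked[0][0]
    superfamily = next(
        (h.mapped_superfamily for h in conflicting_hits if h.mapped_order == order),
        "",
    )
    return order, superfamily, True


def _tree_mean_distances(
    tree, query_id: str, references: Sequence[tuple[str, str, str]]
) -> dict[str, float]:
    """Mean patristic distance from the query to each labeled order group."""
    pdm = tree.phylogenetic_distance_matrix()
    # newick readers may render unquoted underscores as spaces
    taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    if query_id not in taxa:
        return {}
    order_of = {name: order for name, order, _ in references}
    dists: dict[str, list[float]] = {}
    for name, order in order_of.items():
        if name in taxa:
            dists.setdefault(order, []).append(
                pdm.patristic_distance(taxa[query_id], taxa[name])
            )
    return {order: float(np.mean(v)) for order, v in dists.items()}


# ---------------------------------------------------------------------------
# Final classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationRecord:
    """Final taxonomy and curation status for one consensus."""

    consensus_id: str
    te_class: str  # I | II | unknown
    te_order: str
    te_superfamily: str
    family_name: str
    status: str  # curated | relic | expanded_gene | unresolved
    evidence: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.status == "curated" and not (
            self.evidence.get("domain_hit") or self.te_order == "MITE"
        ):
            raise ValueError("curated requires a domain hit or MITE structure")
        if self.status == "relic" and self.evidence.get("domain_hit"):
            raise ValueError("relic cannot carry a domain hit")
        if (
            self.te_order == "DNA/TIR"
            and self.status == "curated"
            and not (self.evidence.get("tir") and self.evidence.get("size_ok"))
        ):
            raise ValueError("curated DNA/TIR requires TIR and size evidence")


def _find_conflicts(
    all_hits: Sequence[ProfileHit], margin: float
) -> list[ProfileHit]:
    """Hits within ``margin`` bits of the best that map to another order."""
    if not all_hits:
        return []
    best = max(all_hits, key=lambda h: h.score)
    near = [h for h in all_hits if h.score >= best.score - margin]
    orders = {h.mapped_order for h in near}
    return near if len(orders) > 1 else []


def classify_consensus(
    record: SequenceRecord,
    order_pred: OrderPrediction,
    best_hit: Optional[ProfileHit],
    all_hits: Sequence[ProfileHit],
    tir: Optional[TIRFeature],
    mask: set[str],
    references: Sequence[tuple[str, str, str]] = (),
    query_domain_seq: str = "",
    external_tree=None,
    conflict_margin: float = DEFAULT_CONFLICT_MARGIN_BITS,
) -> ClassificationRecord:
    """Apply the curation decision cascade to one consensus.

    Decision order: expanded-gene mask, then domain-free branches (MITE /
    relic), then phylogenetic resolution of multi-order domain conflicts,
    then the class II four-criteria rule, and finally agreement between
    order prediction and domain evidence for the remaining orders.
    """
    n = len(record)
    evidence = {
        "order_pred": order_pred.label != "unknown",
        "domain_hit": best_hit is not None,
        "tir": tir is not None,
        "size_ok": True,
        "phylo_resolved": False,
    }
    family = record.id.split("#")[0]

    # (1) chimeric expanded-gene models leave curation entirely
    if record.id in mask:
        return ClassificationRecord(
            record.id, "unknown", "unknown", "", family, "expanded_gene", evidence
        )

    # (2) no transposition domain: MITE structure or relic
    if best_hit is None:
        if tir is not None and MITE_MIN_BP <= n <= MITE_MAX_BP:
            evidence["size_ok"] = True
            return ClassificationRecord(
                record.id, "II", "MITE", "", family, "curated", evidence
            )
        evidence["size_ok"] = False
        return ClassificationRecord(
            record.id, "unknown", "unknown", "", family, "relic", evidence
        )

    # (3) conflicting orders among near-best hits -> tree placement
    order, superfamily = best_hit.mapped_order, best_hit.mapped_superfamily
    conflicts = _find_conflicts(all_hits, conflict_margin)
    if conflicts:
        order, superfamily, resolved = resolve_ambiguous(
            record.id, conflicts, references, query_domain_seq, external_tree
        )
        evidence["phylo_resolved"] = resolved

    # (4) class II DNA/TIR: all four criteria or unresolved
    if order == "DNA/TIR":
        evidence["size_ok"] = DNA_TIR_MIN_BP <= n <= DNA_TIR_MAX_BP
        four = (
            order_pred.label == "DNA"
            and evidence["domain_hit"]
            and evidence["tir"]
            and evidence["size_ok"]
        )
        status = "curated" if four else "unresolved"
        return ClassificationRecord(
            record.id, "II", order, superfamily, family, status, evidence
        )

    # (5) other orders: order prediction must agree with domain evidence
    agree = ORDER_TO_COARSE.get(order) == order_pred.label
    status = "curated" if agree else "unresolved"
    return ClassificationRecord(
        record.id, te_class_of(order), order, superfamily, family, status, evidence
    )


# ---------------------------------------------------------------------------
# Library curation
# ---------------------------------------------------------------------------

def curate_library(
    records: Sequence[SequenceRecord],
    classifications: Sequence[ClassificationRecord],
    out_dir: Optional[str | Path] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame, dict]:
    """Assemble the curated library and its companion tables.

    Returns (curated records renamed ``Family#Order/Superfamily`` in
    RepeatMasker custom-library convention, a per-consensus classification
    table, and a summary of counts by status / class / order /
    superfamily).  When ``out_dir`` is given, writes curated.fasta,
    classification.tsv and summary.json there.
    """
    by_id = {c.consensus_id: c for c in classifications}
    if len(by_id) != len(classifications):
        raise ValueError("duplicate consensus ids in classifications")
    curated: list[SequenceRecord] = []
    rows = []
    for rec in records:
        cls = by_id.get(rec.id)
        if cls is None:
            raise ValueError(f"no classification for {rec.id}")
        if cls.status == "curated":
            suffix = cls.te_order
            if cls.te_superfamily:
                suffix += f"/{cls.te_superfamily}"
            curated.append(
                SequenceRecord(f"{cls.family_name}#{suffix}", rec.seq, rec.description)
            )
        rows.append(
            {
                "consensus_id": cls.consensus_id,
                "te_class": cls.te_class,
                "te_order": cls.te_order,
                "te_superfamily": cls.te_superfamily,
                "family_name": cls.family_name,
                "status": cls.status,
                **{f"evidence_{k}": v for k, v in sorted(cls.evidence.items())},
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_input": len(records),
        "by_status": dict(table["status"].value_counts().sort_index())
        if not table.empty else {},
        "by_class": dict(
            table[table["status"] == "curated"]["te_class"].value_counts().sort_index()
        ) if not table.empty else {},
        "by_order": dict(
            table[table["status"] == "curated"]["te_order"].value_counts().sort_index()
        ) if not table.empty else {},
        "by_superfamily": dict(
            table[(table["status"] == "curated") & (table["te_superfamily"] != "")]
            ["te_superfamily"].value_counts().sort_index()
        ) if not table.empty else {},
        "n_curated": int((table["status"] == "curated").sum()) if not table.empty else 0,
    }
    summary = _jsonify(summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if curated:
            write_fasta(curated, out / "curated.fasta")
        else:
            (out / "curated.fasta").write_text("")
        table.to_csv(out / "classification.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return curated, table, summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
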