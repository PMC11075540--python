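"""Synthetic data with known ground truth for every pipeline stage.

The generator emits the statistical structure the analyses assume: TE
consensus libraries with planted transposition-domain ORFs and terminal
inverted repeats respecting the curation size windows; genomes carrying
family copies mutated to a known Kimura divergence under a
transition/transversion-ratio substitution process; A/B compartment maps
with a configurable excess of aged-copy bp in B; and expression matrices
with controlled gene-TE correlation per compartment plus
differential-expression tables with planted outcome labels.  Every output
is deterministic for a fixed seed and carries a truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tecurate.expression import ExpressionMatrix, UpstreamPair
from tecurate.landscapes import CompartmentMap
from tecurate.seqio import (
    CopyAlignment,
    GenomicInterval,
    RepeatHit,
    SequenceRecord,
    revcomp,
    write_bed,
    write_fasta,
    write_rm_align,
    write_rm_out,
)

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid (standard table, stop codons never emitted)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ("TAA", "TAG", "TGA")

# base compositions giving the three coarse order groups distinct k-mer
# signatures for the naive-Bayes order predictor
COARSE_COMPOSITION = {
    "nonLTR": np.array([0.35, 0.15, 0.15, 0.35]),
    "LTR": np.array([0.15, 0.35, 0.35, 0.15]),
    "DNA": np.array([0.32, 0.28, 0.18, 0.22]),
    "unknown": np.array([0.25, 0.25, 0.25, 0.25]),
}

# simulated domain repertoire: profile name -> (order, superfamily)
SIM_TE_DOMAINS = {
    "RT-Gypsy": ("LTR", "Gypsy"),
    "RT-LINE": ("LINE", ""),
    "YR-DIRS": ("DIRS", ""),
    "YR-Crypton": ("Crypton", ""),
    "transposase-hAT": ("DNA/TIR", "hAT"),
    "transposase-Tc-Mariner": ("DNA/TIR", "Tc-Mariner"),
}
SIM_EXPANDED_DOMAINS = ("Sel1", "BTB", "Kelch", "kinase", "TPR")

ORDER_COARSE = {
    "LTR": "LTR",
    "LINE": "nonLTR",
    "DIRS": "nonLTR",
    "Crypton": "DNA",
    "DNA/TIR": "DNA",
    "MITE": "DNA",
}

ORDER_SIZE_BP = {
    "DNA/TIR": 3_000,
    "MITE": 300,
    "LTR": 4_000,
    "LINE": 3_500,
    "DIRS": 3_500,
    "Crypton": 3_000,
    "relic": 1_500,
    "expanded": 2_000,
}


@dataclass
class GeneratorConfig:
    """Study conditions for every synthetic fixture.

    Defaults mirror the scales of the analyses the toolkit supports: TE
    consensus sizes inside the curation windows, planted divergence of 5%,
    a 2:1 transition/transversion ratio, and per-compartment coexpression
    of 0.2 (A) vs 0.85 (B) over 200 pairs.
    """

    seed: int = 0
    n_families: dict = field(
        default_factory=lambda: {
            "DNA/TIR": 12,
            "MITE": 10,
            "LTR": 10,
            "LINE": 10,
            "Crypton": 8,
            "relic": 10,
            "expanded": 5,
        }
    )
    domain_length_aa: int = 210
    domain_divergence: float = 0.05  # aa-level divergence of planted domains
    tir_length: int = 15
    copy_number: int = 10
    target_divergence: float = 5.0  # percent K2P for genomic copies
    ts_tv_ratio: float = 2.0
    genome_length: int = 300_000
    compartment_fractions: tuple = (0.5, 0.5)
    n_expression_pairs: int = 200
    expression_rho: dict = field(default_factory=lambda: {"A": 0.2, "B": 0.85})


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, composition=None) -> str:
    p = composition if composition is not None else np.full(4, 0.25)
    return "".join(rng.choice(list(BASES), size=n, p=p / np.sum(p)))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def mutate_protein(rng: np.random.Generator, protein: str, frac: float) -> str:
    """Substitute ``frac`` of residues with a different amino acid."""
    chars = list(protein)
    n_mut = int(round(frac * len(chars)))
    sites = rng.choice(len(chars), size=n_mut, replace=False)
    for i in sites:
        choices = [a for a in AA20 if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """Nucleotide coding sequence with uniform synonymous codon choice."""
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def make_domain_alignment(
    rng: np.random.Generator, length: int = 210, n_seqs: int = 5,
    divergence: float = 0.1,
) -> list[str]:
    """An ungapped 'curated alignment' of related domain sequences."""
    base = random_protein(rng, length)
    return [base] + [
        mutate_protein(rng, base, divergence) for _ in range(n_seqs - 1)
    ]


def make_tir(rng: np.random.Generator, length: int) -> tuple[str, str]:
    left = random_dna(rng, length)
    return left, revcomp(left)


# ---------------------------------------------------------------------------
# K2P mutation
# ---------------------------------------------------------------------------

def solve_k2p_proportions(target_k: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Expected (transition, transversion) proportions realizing a K2P
    distance ``target_k`` at a given p/q ratio.

    Inverts K = -1/2 ln((1-2p-q) sqrt(1-2q)) with p = ratio * q.  Raises
    ValueError when the target is beyond saturation for the ratio.
    """
    if target_k < 0:
        raise ValueError("target divergence must be >= 0")
    if target_k == 0:
        return 0.0, 0.0
    r = ts_tv_ratio

    def f(q: float) -> float:
        p = r * q
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        return -0.5 * np.log(w1 * np.sqrt(w2)) - target_k

    q_max = 1.0 / (2.0 * r + 1.0) - 1e-9
    if f(q_max) < 0:
        raise ValueError(f"target K={target_k} unreachable at ratio {r} (saturated)")
    q = brentq(f, 1e-15, q_max)
    return r * q, q


_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
# integer encodings: transition partner and the two transversion partners
_TS_INT = np.array([_BASE_TO_INT[_TRANSITION_OF[b]] for b in BASES])
_TV_INT = np.array([[_BASE_TO_INT[c] for c in _TRANSVERSIONS_OF[b]] for b in BASES])


def mutate_k2p(
    seq: str,
    target_k: float,
    ts_tv_ratio: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, int, int]:
    """Mutate a sequence to an expected K2P divergence of ``target_k``.

    Sites are substituted independently: transition with probability p,
    transversion (either partner equally) with probability q, where (p, q)
    solve the K2P closed form at the requested ratio.  Returns the mutated
    copy and the realized transition/transversion counts.
    """
    rng = rng or np.random.default_rng()
    p, q = solve_k2p_proportions(target_k, ts_tv_ratio)
    code = np.array([_BASE_TO_INT[b] for b in seq], dtype=np.int64)
    u = rng.random(len(code))
    out = code.copy()
    ts_mask = u < p
    tv_mask = (u >= p) & (u < p + q)
    out[ts_mask] = _TS_INT[code[ts_mask]]
    which = rng.integers(2, size=int(tv_mask.sum()))
    out[tv_mask] = _TV_INT[code[tv_mask], which]
    mutated = "".join(BASES[i] for i in out)
    return mutated, int(ts_mask.sum()), int(tv_mask.sum())


# ---------------------------------------------------------------------------
# TE family generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    """A consensus library with its ground truth and domain alignments."""

    records: list[SequenceRecord]
    truth: pd.DataFrame  # consensus_id, true_order, true_superfamily, ...
    te_domain_alignments: dict[str, list[str]]  # profile name -> alignment
    expanded_alignments: dict[str, list[str]]
    training_records: list[SequenceRecord]
    training_labels: list[str]


def gen_te_family(
    rng: np.random.Generator,
    order: str,
    superfamily: str,
    family_id: str,
    domain_alignment: Optional[Sequence[str]] = None,
    size_bp: Optional[int] = None,
    tir_length: int = 15,
    domain_divergence: float = 0.05,
) -> tuple[SequenceRecord, dict]:
    """One consensus with the structural/domain features of its order.

    Domain-bearing orders embed a back-translated copy of the domain
    consensus (mutated at ``domain_divergence`` on the amino-acid level)
    as an intact stop-flanked ORF.  DNA/TIR and MITE orders get exact
    terminal inverted repeats; MITE and relic modes carry no domain.
    Raises ValueError when the requested size violates the order's window.
    """
    size = size_bp if size_bp is not None else ORDER_SIZE_BP[order]
    if order == "MITE" and not 50 <= size <= 1_000:
        raise ValueError("MITE size must be in [50, 1000] bp")
    if order == "DNA/TIR" and not 1_000 <= size <= 17_000:
        raise ValueError("DNA/TIR size must be in [1000, 17000] bp")

    comp = COARSE_COMPOSITION[ORDER_COARSE.get(order, "unknown")]
    needs_tir = order in {"DNA/TIR", "MITE"}
    has_domain = domain_alignment is not None and order not in {"MITE", "relic"}

    left_tir = right_tir = ""
    if needs_tir:
        left_tir, right_tir = make_tir(rng, tir_length)

    orf_nt = ""
    if has_domain:
        domain_protein = mutate_protein(rng, domain_alignment[0], domain_divergence)
        orf_nt = _STOPS[rng.integers(3)] + back_translate(rng, domain_protein) \
            + _STOPS[rng.integers(3)]

    filler = size - len(left_tir) - len(right_tir) - len(orf_nt)
    if filler < 0:
        raise ValueError(f"size {size} too small for planted features")
    pre = rng.integers(filler + 1)
    seq = (
        left_tir
        + random_dna(rng, int(pre), comp)
        + orf_nt
        + random_dna(rng, int(filler - pre), comp)
        + right_tir
    )
    record = SequenceRecord(family_id, seq)
    truth = {
        "consensus_id": family_id,
        "true_order": order,
        "true_superfamily": superfamily,
        "true_class": "II" if order in {"DNA/TIR", "MITE", "Crypton"} else "I",
        "tir_length": tir_length if needs_tir else 0,
        "has_domain": has_domain,
        "length_bp": len(seq),
    }
    return record, truth


def gen_library(config: GeneratorConfig) -> SimulatedLibrary:
    """A full consensus library spanning the curation decision space.

    Includes domain-bearing class I and class II families, MITEs, relics
    (no domain, no MITE-compatible structure), and expanded-gene chimeras
    whose ORF matches a host gene profile instead of a TE domain.
    """
    rng = np.random.default_rng(config.seed)
    te_aligns = {
        name: make_domain_alignment(rng, config.domain_length_aa)
        for name in sorted(SIM_TE_DOMAINS)
    }
    exp_aligns = {
        name: make_domain_alignment(rng, config.domain_length_aa)
        for name in SIM_EXPANDED_DOMAINS
    }
    # domain assignment per order
    order_domains = {
        "LTR": "RT-Gypsy",
        "LINE": "RT-LINE",
        "DIRS": "YR-DIRS",
        "Crypton": "YR-Crypton",
        "DNA/TIR": "transposase-hAT",
    }
    order_superfamilies = {
        "LTR": "Gypsy", "LINE": "", "DIRS": "", "Crypton": "", "DNA/TIR": "hAT",
    }

    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    fam_counter = 0
    for order in sorted(config.n_families):
        for _ in range(config.n_families[order]):
            fam_counter += 1
            fid = f"rnd1_fam{fam_counter}"
            if order == "relic":
                rec, row = gen_te_family(
                    rng, "relic", "", fid, None,
                    size_bp=ORDER_SIZE_BP["relic"],
                    domain_divergence=config.domain_divergence,
                )
                row["true_status"] = "relic"
                row["true_order"] = "unknown"
            elif order == "expanded":
                name = SIM_EXPANDED_DOMAINS[fam_counter % len(SIM_EXPANDED_DOMAINS)]
                rec, row = gen_te_family(
                    rng, "expanded", "", fid, exp_aligns[name],
                    size_bp=ORDER_SIZE_BP["expanded"],
                    domain_divergence=config.domain_divergence,
                )
                row["true_status"] = "expanded_gene"
                row["true_order"] = "unknown"
                row["has_domain"] = False  # no TE domain
            elif order == "MITE":
                rec, row = gen_te_family(
                    rng, "MITE", "", fid, None,
                    tir_length=config.tir_length,
                )
                row["true_status"] = "curated"
            else:
                rec, row = gen_te_family(
                    rng, order, order_superfamilies[order], fid,
                    te_aligns[order_domains[order]],
                    tir_length=config.tir_length,
                    domain_divergence=config.domain_divergence,
                )
                row["true_status"] = "curated"
            records.append(rec)
            truth_rows.append(row)

    # labeled training set for the k-mer order predictor
    training_records: list[SequenceRecord] = []
    training_labels: list[str] = []
    for coarse in ("nonLTR", "LTR", "DNA"):
        for i in range(30):
            training_records.append(
                SequenceRecord(
                    f"train_{coarse}_{i}",
                    random_dna(rng, 2_000, COARSE_COMPOSITION[coarse]),
                )
            )
            training_labels.append(coarse)

    return SimulatedLibrary(
        records=records,
        truth=pd.DataFrame(truth_rows),
        te_domain_alignments=te_aligns,
        expanded_alignments=exp_aligns,
        training_records=training_records,
        training_labels=training_labels,
    )


def gen_expanded_chimera(*args, **kwargs):  # pragma: no cover - thin alias
    return gen_te_family(*args, **kwargs)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    genome: SequenceRecord
    hits: list[RepeatHit]
    copies: list[CopyAlignment]
    align_blocks: list[tuple[GenomicInterval, str, str, str]]
    compartments: CompartmentMap
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], out / "genome.fasta")
        write_rm_out(self.hits, out / "copies.out")
        write_rm_align(
            out / "copies.align", self.align_blocks,
            genome_sizes={self.genome.id: len(self.genome)},
        )
        write_bed(self.compartments.intervals, out / "compartments.bed")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def gen_genome(
    config: GeneratorConfig,
    families: Optional[Sequence[SequenceRecord]] = None,
    divergence_by_compartment: Optional[dict[str, Sequence[float]]] = None,
    copy_length: int = 500,
) -> SimulatedGenome:
    """A single-chromosome genome with planted, divergence-controlled copies.

    The chromosome is split into an A compartment (first fraction) and a B
    compartment (remainder).  ``divergence_by_compartment`` maps "A"/"B"
    to the list of target percent divergences, one per copy to plant
    there; by default each compartment receives ``copy_number`` copies per
    family at ``target_divergence``.  Copies are placed non-overlapping
    with random spacing; the ``.align`` blocks written are exactly the
    planted copy/consensus alignments.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    fa = config.compartment_fractions[0]
    a_span = GenomicInterval("chr1", 0, int(L * fa), ".", "A")
    b_span = GenomicInterval("chr1", int(L * fa), L, ".", "B")
    comp_map = CompartmentMap((a_span, b_span))

    if families is None:
        families = [
            SequenceRecord(f"simfam{i + 1}", random_dna(rng, copy_length))
            for i in range(3)
        ]
    if divergence_by_compartment is None:
        per_comp = config.copy_number * len(families)
        divergence_by_compartment = {
            "A": [config.target_divergence] * per_comp,
            "B": [config.target_divergence] * per_comp,
        }

    genome = np.array(list(random_dna(rng, L)))
    hits: list[RepeatHit] = []
    copies: list[CopyAlignment] = []
    blocks: list[tuple[GenomicInterval, str, str, str]] = []
    truth_rows: list[dict] = []

    for comp_label, span in (("A", a_span), ("B", b_span)):
        targets = list(divergence_by_compartment.get(comp_label, ()))
        if not targets:
            continue
        room = len(span) - sum(
            len(families[i % len(families)]) for i in range(len(targets))
        )
        if room < len(targets):
            raise ValueError(f"compartment {comp_label} too small for copies")
        gaps = rng.multinomial(room - len(targets), np.full(len(targets), 1 / len(targets)))
        cursor = span.start
        for i, target in enumerate(targets):
            fam = families[i % len(families)]
            cursor += int(gaps[i]) + 1
            start, end = cursor, cursor + len(fam)
            if end > span.end:
                raise ValueError(f"compartment {comp_label} overflow")
            mutated, ts, tv = mutate_k2p(
                fam.seq, target / 100.0, config.ts_tv_ratio, rng
            )
            genome[start:end] = list(mutated)
            iv = GenomicInterval("chr1", start, end, "+", fam.id)
            sites = len(fam)
            div_pct = 100.0 * (ts + tv) / sites
            hits.append(
                RepeatHit(iv, fam.id, "Unknown", float(sites), div_pct)
            )
            copies.append(CopyAlignment(iv, fam.id, sites, ts, tv))
            blocks.append((iv, fam.id, mutated, fam.seq))
            truth_rows.append(
                {
                    "family": fam.id,
                    "compartment": comp_label,
                    "start": start,
                    "end": end,
                    "target_divergence_pct": target,
                    "realized_ts": ts,
                    "realized_tv": tv,
                }
            )
            cursor = end
    return SimulatedGenome(
        genome=SequenceRecord("chr1", "".join(genome)),
        hits=hits,
        copies=copies,
        align_blocks=blocks,
        compartments=comp_map,
        truth=pd.DataFrame(truth_rows),
    )


def gen_compartment_scenario(
    config: GeneratorConfig,
    n_young_per_comp: int = 60,
    n_old_a: int = 60,
    n_old_b: int = 120,
    copy_length: int = 500,
) -> SimulatedGenome:
    """An A/B genome emulating preferential retention of old TEs in B.

    Both compartments receive the same number of young copies (0-8%
    divergence); the B compartment receives twice the aged-copy bp
    (uniform 10.5-19.5% divergence), so per-bin percentages over bins
    10-20 are higher in B.
    """
    rng = np.random.default_rng(config.seed + 2)
    young = lambda n: list(rng.uniform(0.5, 8.0, size=n))
    old = lambda n: list(rng.uniform(10.5, 19.5, size=n))
    div = {
        "A": young(n_young_per_comp) + old(n_old_a),
        "B": young(n_young_per_comp) + old(n_old_b),
    }
    return gen_genome(config, divergence_by_compartment=div, copy_length=copy_length)


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExpression:
    expression: ExpressionMatrix
    pairs: list[UpstreamPair]
    strata: dict[str, str]  # gene_id -> compartment
    de_table: pd.DataFrame
    truth: pd.DataFrame


def gen_expression(
    config: GeneratorConfig,
    n_samples: int = 3,
    n_up: int = 40,
    n_down: int = 10,
    n_no: int = 50,
) -> SimulatedExpression:
    """Gene-TE pair abundances with per-stratum correlation plus a DE table.

    For each compartment stratum, ``n_expression_pairs`` gene-TE pairs get
    log-abundances drawn from a bivariate normal with the stratum's true
    correlation; TPM values are exp(log-abundance) - 1 so the toolkit's
    ln(TPM + 1) transform recovers the planted scale.  The DE table plants
    exact UP/DOWN/NO outcomes (padj <= 0.05 with signed log2 fold change).
    """
    rng = np.random.default_rng(config.seed + 3)
    feature_ids: list[str] = []
    values: list[np.ndarray] = []
    pairs: list[UpstreamPair] = []
    strata: dict[str, str] = {}
    truth_rows: list[dict] = []
    offset = 0
    for comp in sorted(config.expression_rho):
        rho = config.expression_rho[comp]
        if not -1.0 < rho < 1.0:
            raise ValueError(f"|rho| must be < 1, got {rho}")
        n = config.n_expression_pairs
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([3.0, 3.0], cov, size=n)
        for i in range(n):
            gid = f"gene_{comp}_{i}"
            tid = f"te_{comp}_{i}"
            g_tpm = max(np.expm1(z[i, 0]), 0.0)
            t_tpm = max(np.expm1(z[i, 1]), 0.0)
            feature_ids.extend([gid, tid])
            values.append(np.full(n_samples, g_tpm))
            values.append(np.full(n_samples, t_tpm))
            gene_start = offset + 10_000 * (i + 1)
            gene_iv = GenomicInterval("chrE", gene_start, gene_start + 2_000, "+", gid)
            te_end = gene_start - int(rng.integers(0, 1_001))
            te_iv = GenomicInterval("chrE", te_end - 400, te_end, "+", tid)
            pairs.append(
                UpstreamPair(gid, tid, gene_start - te_end, te_iv, gene_iv)
            )
            strata[gid] = comp
            truth_rows.append(
                {"gene_id": gid, "te_id": tid, "stratum": comp, "true_rho": rho}
            )
        offset += 10_000 * (config.n_expression_pairs + 2)

    matrix = ExpressionMatrix(
        pd.DataFrame(
            np.vstack(values),
            index=feature_ids,
            columns=[f"sample_{j + 1}" for j in range(n_samples)],
        ),
        feature_lengths=pd.Series(1_000.0, index=feature_ids),
        unit="TPM",
    )

    de_rows = []
    for i in range(n_up):
        de_rows.append((f"feat_up_{i}", float(rng.uniform(1, 5)),
                        float(rng.uniform(0, 0.05)), "UP"))
    for i in range(n_down):
        de_rows.append((f"feat_down_{i}", float(-rng.uniform(1, 5)),
                        float(rng.uniform(0, 0.05)), "DOWN"))
    for i in range(n_no):
        de_rows.append((f"feat_no_{i}", float(rng.normal(0, 1)),
                        float(rng.uniform(0.0501, 1.0)), "NO"))
    de_table = pd.DataFrame(
        de_rows, columns=["feature_id", "log2_fold_change", "padj", "true_label"]
    )
    return SimulatedExpression(
        expression=matrix,
        pairs=pairs,
        strata=strata,
        de_table=de_table,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_simulation(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Generate and write every fixture family to ``out_dir``.

    Returns a manifest of the files written; identical configs produce
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = gen_library(config)
    write_fasta(lib.records, out / "library.fasta")
    lib.truth.to_csv(out / "library_truth.tsv", sep="\t", index=False)
    genome = gen_compartment_scenario(config)
    genome.write(out / "genome")
    expr = gen_expression(config)
    expr.expression.to_tsv(out / "expression_tpm.tsv")
    expr.de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    expr.truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "files": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
        "n_families": int(len(lib.records)),
        "n_copies": int(len(genome.copies)),
        "n_pairs": int(len(expr.pairs)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
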