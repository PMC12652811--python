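"""Seed-deterministic synthetic data for every pipeline stage.

Three generators, all pure functions of their arguments (including the
seed; a single :class:`numpy.random.Generator` stream per call, no global
state):

* :func:`gen_proteome` — i.i.d. background proteomes with motif instances
  planted at recorded, mutually non-overlapping coordinates, so scanner
  recall can be measured against exact ground truth;
* :func:`gen_annotation_table` — annotation tables with one planted
  over-represented term among >=10 decoy terms at background rate, for
  exercising the enrichment statistic on a known fold;
* :func:`gen_edge_table` — weighted edge tables with dense high-score
  modules and sparse low-score inter-module noise, for exercising edge
  filtering and MCL module recovery.

The proteomes emulate residue composition and length dispersion only; they
carry none of the domain structure, repeats or homology of a real
proteome, so planted-truth recall says nothing about biological precision
on real sequences.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motifs import CANONICAL_AA, MotifPattern, load_motif_set
from .network import Edge
from .proteome_io import SequenceRecord, _open_write

#: Approximate human-proteome residue frequencies (SwissProt-like
#: composition, normalized to sum to 1).
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0572, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}

UNIFORM_AA_FREQS: dict[str, float] = {a: 1.0 / 20.0 for a in sorted(CANONICAL_AA)}


@dataclass(frozen=True)
class SimSpec:
    """Specification of a synthetic proteome.

    Lengths are drawn log-normal with the given mean and standard
    deviation (of the lengths themselves), floored at the widest planted
    motif's maximal span plus 10 residues so every sequence can host an
    instance.  ``plants`` lists (motif_name, n_instances) pairs resolved
    against the default motif set unless patterns are passed explicitly to
    :func:`gen_proteome`.
    """

    n_sequences: int
    length_mean: float = 1000.0
    length_sd: float = 300.0
    residue_freqs: Mapping[str, float] | None = None  # None -> uniform
    plants: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0:
            raise ValueError("n_sequences must be positive")
        if any(n < 0 for _, n in self.plants):
            raise ValueError("n_instances must be >= 0")
        freqs = self.frequencies
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("residue frequencies must sum to 1")

    @property
    def frequencies(self) -> Mapping[str, float]:
        return self.residue_freqs if self.residue_freqs is not None else UNIFORM_AA_FREQS


@dataclass(frozen=True)
class PlantedInstance:
    """Ground-truth coordinates of one planted motif instance (1-based,
    inclusive)."""

    seq_id: str
    motif_name: str
    start: int
    end: int


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # mu/sigma of the underlying normal from the target mean/sd of lengths
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _realize_instance(
    motif: MotifPattern, rng: np.random.Generator, letters: list[str], probs: np.ndarray
) -> str:
    parts: list[str] = []
    for el in motif.elements:
        if el.kind == "anchor":
            choices = sorted(el.allowed)
            parts.append(choices[int(rng.integers(len(choices)))])
        else:
            g = int(rng.integers(el.min_len, el.max_len + 1))
            if g:
                parts.append("".join(rng.choice(letters, size=g, p=probs)))
    return "".join(parts)


def gen_proteome(
    spec: SimSpec, motifs: Mapping[str, MotifPattern] | None = None
) -> tuple[list[SequenceRecord], list[PlantedInstance]]:
    """Generate a background proteome with planted motif instances.

    Background residues are i.i.d. from ``spec.residue_freqs``; each
    planted instance samples its gap lengths uniformly within range, its
    anchor residues uniformly from their classes and its gap residues from
    the background, and is spliced (overwritten) into a uniformly chosen
    sequence at a uniformly chosen offset that does not overlap any other
    planted instance.  Raises if placement fails after bounded retries.
    """
    if motifs is None:
        motifs = load_motif_set()
    for name, _ in spec.plants:
        if name not in motifs:
            raise KeyError(f"planted motif {name!r} not in the motif set")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies
    letters = sorted(freqs)
    probs = np.asarray([freqs[a] for a in letters])
    probs = probs / probs.sum()

    widest = max((motifs[name].span_max for name, _ in spec.plants), default=20)
    floor = widest + 10
    mu, sigma = _lognormal_params(spec.length_mean, spec.length_sd)
    lengths = np.maximum(
        np.round(rng.lognormal(mu, sigma, size=spec.n_sequences)).astype(int), floor
    )
    width = max(4, len(str(spec.n_sequences)))
    seq_ids = [f"SYN{i + 1:0{width}d}" for i in range(spec.n_sequences)]
    sequences = [
        list(rng.choice(letters, size=int(length), p=probs)) for length in lengths
    ]

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_sequences)}
    truth: list[PlantedInstance] = []
    for motif_name, n_instances in spec.plants:
        motif = motifs[motif_name]
        for _ in range(n_instances):
            placed = False
            for _attempt in range(1000):
                instance = _realize_instance(motif, rng, letters, probs)
                si = int(rng.integers(spec.n_sequences))
                seq = sequences[si]
                if len(seq) < len(instance):
                    continue
                off = int(rng.integers(len(seq) - len(instance) + 1))
                lo, hi = off + 1, off + len(instance)  # 1-based inclusive
                if any(lo <= e and s <= hi for s, e in occupied[si]):
                    continue
                seq[off : off + len(instance)] = list(instance)
                occupied[si].append((lo, hi))
                truth.append(PlantedInstance(seq_ids[si], motif_name, lo, hi))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {motif_name} instance without overlap"
                )
    records = [
        SequenceRecord(seq_id, f"synthetic background sequence {i + 1}", "".join(seq))
        for i, (seq_id, seq) in enumerate(zip(seq_ids, sequences))
    ]
    truth.sort(key=lambda t: (t.seq_id, t.motif_name, t.start))
    return records, truth


def count_background_hits(matches, truth: Sequence[PlantedInstance]) -> dict[str, int]:
    """Count scan hits per motif that do not overlap any planted instance
    of the same motif in the same sequence.

    Hits overlapping a planted interval are alternative spans induced by
    the planted anchors, not independent background events, so only
    non-overlapping hits are comparable with the i.i.d. background
    expectation from :func:`abascan.motifs.expected_match_count`.
    """
    planted: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in truth:
        planted.setdefault((t.seq_id, t.motif_name), []).append((t.start, t.end))
    counts: dict[str, int] = {}
    for m in matches:
        intervals = planted.get((m.seq_id, m.motif_name), [])
        if not any(m.start <= e and s <= m.end for s, e in intervals):
            counts[m.motif_name] = counts.get(m.motif_name, 0) + 1
    return counts


def write_truth_tsv(truth: Sequence[PlantedInstance], dest) -> None:
    """Write planted-instance ground truth as ``seq_id motif start end`` TSV."""
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["seq_id", "motif", "start", "end"])
        for t in truth:
            writer.writerow([t.seq_id, t.motif_name, t.start, t.end])


def gen_annotation_table(
    candidate_ids: Iterable[str],
    background_ids: Iterable[str],
    planted_term_fold: float,
    seed: int,
    base_rate: float = 0.05,
    n_decoys: int = 20,
):
    """Annotation table with one planted enriched term and decoys.

    The planted term takes ``round(fold * base_rate * n)`` candidates and
    ``round(base_rate * (N - n))`` non-candidates (membership random,
    counts fixed), so its realized fold tracks ``planted_term_fold``.
    Decoy terms sample ``round(base_rate * N)`` members uniformly from the
    background.  Raises when the fold is unattainable (candidate rate
    above 1, or candidates identical to the background, where every term
    has fold exactly 1).
    """
    from .enrichment import AnnotationTable

    cand = sorted(set(candidate_ids))
    bg = sorted(set(background_ids))
    if not set(cand) <= set(bg):
        raise ValueError("candidate ids must be a subset of the background")
    if planted_term_fold <= 1:
        raise ValueError("planted_term_fold must exceed 1")
    if len(cand) == len(bg):
        raise ValueError("fold > 1 unattainable when candidates equal the background")
    cand_rate = planted_term_fold * base_rate
    if cand_rate > 1:
        raise ValueError(
            f"fold {planted_term_fold} unattainable at base rate {base_rate}"
        )
    if n_decoys < 10:
        raise ValueError("at least 10 decoy terms are required")
    rng = np.random.default_rng(seed)
    non_cand = sorted(set(bg) - set(cand))
    k = max(1, round(cand_rate * len(cand)))
    k_bg = round(base_rate * len(non_cand))
    terms: dict[str, frozenset[str]] = {}
    planted = set(rng.choice(cand, size=k, replace=False)) | set(
        rng.choice(non_cand, size=k_bg, replace=False)
    )
    terms["PLANTED"] = frozenset(planted)
    decoy_size = max(1, round(base_rate * len(bg)))
    for d in range(n_decoys):
        members = rng.choice(bg, size=decoy_size, replace=False)
        terms[f"DECOY_{d + 1:02d}"] = frozenset(members)
    return AnnotationTable(terms, frozenset(bg))


def write_annotation_tsv(table, dest) -> None:
    """Write an annotation table in long ``term seq_id`` TSV format."""
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term", "seq_id"])
        for term in sorted(table.terms):
            for seq_id in sorted(table.terms[term]):
                writer.writerow([term, seq_id])


def gen_edge_table(
    module_sizes: Sequence[int],
    intra_range: tuple[float, float] = (0.85, 1.0),
    inter_range: tuple[float, float] = (0.0, 0.3),
    seed: int = 0,
    inter_prob: float = 0.3,
) -> tuple[list[Edge], list[list[str]]]:
    """Edge table with planted high-score modules plus noise edges.

    Each module is a complete subgraph with combined scores uniform on
    ``intra_range``; each inter-module pair gets an edge with probability
    ``inter_prob`` and a score uniform on ``inter_range``.  The
    co-expression channel mirrors the combined score.  Returns the edges
    and the planted module memberships.
    """
    if intra_range[0] <= inter_range[1]:
        raise ValueError("intra_range must lie strictly above inter_range")
    rng = np.random.default_rng(seed)
    modules = [
        [f"M{mi}_{ni:02d}" for ni in range(size)]
        for mi, size in enumerate(module_sizes)
    ]
    edges: list[Edge] = []

    def add(a: str, b: str, lo: float, hi: float) -> None:
        score = float(rng.uniform(lo, hi))
        edges.append(Edge(a, b, score, {"coexpression": score}))

    for members in modules:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add(members[i], members[j], *intra_range)
    for mi in range(len(modules)):
        for mj in range(mi + 1, len(modules)):
            for a in modules[mi]:
                for b in modules[mj]:
                    if rng.uniform() < inter_prob:
                        add(a, b, *inter_range)
    return edges, modules


def write_edge_tsv(edges: Sequence[Edge], dest) -> None:
    """Write edges in the STRING-export TSV dialect (0–1 float scores)."""
    channels = sorted({ch for e in edges for ch in e.channel_scores})
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node1", "node2", *channels, "combined_score"])
        for e in sorted(edges, key=lambda e: (e.node_a, e.node_b)):
            writer.writerow(
                [e.node_a, e.node_b]
                + [f"{e.channel_scores.get(ch, 0.0):.6g}" for ch in channels]
                + [f"{e.combined:.6g}"]
            )
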