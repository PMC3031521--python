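"""PIN-based protein function inference (FunScore with permutation p-values).

Function annotations transfer across the interaction network by weighted
averaging: a protein's direct (level-1) neighbors vote with their
Czekanowski-Dice similarity S1, its indirect (level-2) neighbors vote with a
transitive similarity S2, and a background term keeps scores calibrated for
poorly connected proteins.  For protein p and function x,

    FunScore(p, x) = [ lambda*r_int*pi_x
                       + sum_{v in L1(p)} S1(p, v) * delta(v, x)
                       + sum_{w in L2(p)} S2(p, w) * delta(w, x) ] / Z

    Z = lambda*r_int + sum_{v in L1(p)} S1(p, v) + sum_{w in L2(p)} S2(p, w)

where delta(v, x) = 1 iff v is annotated with x, pi_x is the frequency of x
among annotated proteins, r_int is the fraction of annotated-annotated edges
whose endpoints share a function, and lambda = 1.  Z is shared across terms
for a given protein, so scores lie in [0, 1].

S1 uses inclusive neighborhoods: with N_u = {u} ∪ adjacent(u),
S1(u, v) = 2|N_u ∩ N_v| / (|N_u| + |N_v|) = 1 - CD-distance(u, v).
S2 sums S1-products over shared intermediate neighbors, capped at 1 (a
max-over-intermediates variant is available behind a flag).

Candidate protein-function pairs pass a preliminary score cutoff (0.03) and
are then tested against a permutation null that shuffles whole annotation
sets over the annotated proteins with the network fixed, preserving both
per-protein annotation counts and global term frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_model import (
    AnnotationMap,
    InteractionNetwork,
    ValidationError,
)

__all__ = [
    "FunScoreParams",
    "FunScoreRecord",
    "FunScoreResult",
    "compute_funscore_params",
    "neighborhood",
    "cd_similarity",
    "transitive_similarity",
    "fun_score",
    "predict_functions",
    "permutation_pvalues",
]

P_SIGNIFICANT = 0.05


@dataclass(frozen=True)
class FunScoreParams:
    """Background model and filtration settings for FunScore."""

    r_int: float
    pi: dict[str, float]
    lambda_weight: float = 1.0
    cutoff: float = 0.03
    n_perm: int = 10_000
    seed: int = 0
    transitive: str = "sum"  # or "max": aggregation over shared intermediates

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_int <= 1.0:
            raise ValidationError(f"r_int={self.r_int} outside [0,1]")
        if any(not 0.0 <= v <= 1.0 for v in self.pi.values()):
            raise ValidationError("pi values must lie in [0,1]")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.transitive not in ("sum", "max"):
            raise ValidationError(f"unknown transitive mode {self.transitive!r}")


@dataclass
class FunScoreRecord:
    protein_id: str
    term_id: str
    score: float
    candidate: bool  # passed the score cutoff
    p_value: float | None = None
    significant: bool = False


@dataclass
class FunScoreResult:
    records: list[FunScoreRecord]

    def for_protein(self, protein_id: str) -> list[FunScoreRecord]:
        return [r for r in self.records if r.protein_id == protein_id]

    def top_term(self, protein_id: str) -> str | None:
        recs = self.for_protein(protein_id)
        if not recs:
            return None
        return max(recs, key=lambda r: (r.score, r.term_id)).term_id

    @property
    def candidates(self) -> list[FunScoreRecord]:
        return [r for r in self.records if r.candidate]


def compute_funscore_params(
    net: InteractionNetwork,
    ann: AnnotationMap,
    **overrides,
) -> FunScoreParams:
    """Estimate r_int and the background term frequencies pi from the data.

    r_int counts only edges whose two endpoints are both annotated; pi_x is
    the fraction of annotated proteins carrying term x.
    """
    annotated = ann.annotated_proteins
    shared = total = 0
    for e in net.edges:
        u, v = tuple(e)
        if u in annotated and v in annotated:
            total += 1
            if ann.terms_of(u) & ann.terms_of(v):
                shared += 1
    r_int = shared / total if total else 0.0
    n_ann = len(annotated)
    pi = {
        t: sum(1 for p in annotated if t in ann.terms_of(p)) / n_ann
        for t in ann.terms
    } if n_ann else {}
    return FunScoreParams(r_int=r_int, pi=pi, **overrides)


def neighborhood(net: InteractionNetwork, p: str, level: str = "N_incl") -> set[str]:
    """Neighborhood of p: inclusive (``N_incl``), direct (``L1``) or
    distance-2 (``L2``)."""
    adj = net.neighbors(p)  # validates membership
    if level == "N_incl":
        return {p} | adj
    if level == "L1":
        return adj
    if level == "L2":
        two = set()
        for v in adj:
            two |= net.neighbors(v)
        return two - adj - {p}
    raise ValidationError(f"unknown neighborhood level {level!r}")


def cd_similarity(net: InteractionNetwork, u: str, v: str) -> float:
    """Czekanowski-Dice similarity 1 - D over inclusive neighborhoods."""
    nu = neighborhood(net, u, "N_incl")
    nv = neighborhood(net, v, "N_incl")
    return 2.0 * len(nu & nv) / (len(nu) + len(nv))


def transitive_similarity(
    net: InteractionNetwork, u: str, v: str, mode: str = "sum"
) -> float:
    """Similarity via shared intermediates: products S1(u,w)*S1(w,v).

    ``sum`` mode adds the products over all shared level-1 neighbors w (not u
    or v themselves) and caps the total at 1; ``max`` takes the best single
    intermediate.  Symmetric in u and v.
    """
    common = (net.neighbors(u) & net.neighbors(v)) - {u, v}
    if not common:
        return 0.0
    products = [cd_similarity(net, u, w) * cd_similarity(net, w, v) for w in common]
    if mode == "sum":
        return min(1.0, sum(products))
    if mode == "max":
        return max(products)
    raise ValidationError(f"unknown transitive mode {mode!r}")


def _score_components(
    net: InteractionNetwork, params: FunScoreParams, p: str
) -> tuple[list[tuple[str, float]], float]:
    """Per-neighbor vote weights for p and the shared normalizer Z."""
    l1 = neighborhood(net, p, "L1")
    l2 = neighborhood(net, p, "L2")
    weights = [(v, cd_similarity(net, p, v)) for v in sorted(l1)]
    weights += [
        (w, transitive_similarity(net, p, w, mode=params.transitive))
        for w in sorted(l2)
    ]
    base = params.lambda_weight * params.r_int
    z = base + sum(w for _, w in weights)
    return weights, z


def fun_score(
    net: InteractionNetwork,
    ann: AnnotationMap,
    params: FunScoreParams,
    p: str,
    x: str,
) -> float:
    """FunScore(p, x) in [0, 1]; NaN if the normalizer Z is zero."""
    if x not in params.pi:
        raise ValidationError(f"term {x!r} absent from the background table")
    weights, z = _score_components(net, params, p)
    if z == 0.0:
        return float("nan")
    num = params.lambda_weight * params.r_int * params.pi[x]
    for v, w in weights:
        if x in ann.terms_of(v):
            num += w
    return num / z


def predict_functions(
    net: InteractionNetwork,
    ann: AnnotationMap,
    params: FunScoreParams,
    targets: set[str],
) -> FunScoreResult:
    """Score every (target, term) pair with positive background frequency.

    Terms carried by the target's level-1/level-2 neighborhood receive
    neighbor votes; all other terms score lambda*r_int*pi_x / Z.  Pairs with
    score >= cutoff are flagged as candidates for permutation testing.
    """
    unknown = targets - net.nodes
    if unknown:
        raise ValidationError(f"targets not in network: {sorted(unknown)[:5]}")
    terms = sorted(t for t, f in params.pi.items() if f > 0)
    records: list[FunScoreRecord] = []
    base = params.lambda_weight * params.r_int
    for p in sorted(targets):
        weights, z = _score_components(net, params, p)
        if z == 0.0:
            continue  # isolated protein with no background weight: undefined
        votes: dict[str, float] = {}
        for v, w in weights:
            for t in ann.terms_of(v):
                votes[t] = votes.get(t, 0.0) + w
        for t in terms:
            score = (base * params.pi[t] + votes.get(t, 0.0)) / z
            records.append(
                FunScoreRecord(p, t, score, candidate=score >= params.cutoff)
            )
    return FunScoreResult(records)


def permutation_pvalues(
    net: InteractionNetwork,
    ann: AnnotationMap,
    params: FunScoreParams,
    candidates: FunScoreResult,
) -> FunScoreResult:
    """Empirical p-values for candidate pairs under annotation-set shuffling.

    Each permutation reassigns the per-protein annotation sets over the
    annotated proteins (the network and the score weights stay fixed), and
    every candidate pair's FunScore is recomputed; p = (1 + #{permuted score
    >= observed}) / (n_perm + 1).  A pair is significant when p < 0.05 and
    its observed score passes the cutoff.
    """
    cand = [r for r in candidates.records if r.candidate]
    if not cand:
        return FunScoreResult(list(candidates.records))
    annotated = sorted(ann.annotated_proteins)
    ann_index = {p: i for i, p in enumerate(annotated)}
    term_list = sorted({r.term_id for r in cand} | ann.terms)
    term_index = {t: j for j, t in enumerate(term_list)}
    # per-protein annotation-set membership matrix (annotated proteins x terms)
    member = np.zeros((len(annotated), len(term_list)), dtype=float)
    for i, p in enumerate(annotated):
        for t in ann.terms_of(p):
            member[i, term_index[t]] = 1.0

    # weight matrix: candidate targets x annotated proteins, plus shared Z
    target_ids = sorted({r.protein_id for r in cand})
    w_matrix = np.zeros((len(target_ids), len(annotated)))
    z_vec = np.zeros(len(target_ids))
    base = params.lambda_weight * params.r_int
    for ti, p in enumerate(target_ids):
        weights, z = _score_components(net, params, p)
        z_vec[ti] = z
        for v, w in weights:
            if v in ann_index:
                w_matrix[ti, ann_index[v]] += w

    t_idx = {p: i for i, p in enumerate(target_ids)}
    pi_vec = np.array([params.pi.get(t, 0.0) for t in term_list])
    rng = np.random.default_rng(params.seed)
    exceed = np.zeros(len(cand))
    obs = np.array([r.score for r in cand])
    rows = np.array([t_idx[r.protein_id] for r in cand])
    cols = np.array([term_index[r.term_id] for r in cand])
    for _ in range(params.n_perm):
        perm = rng.permutation(len(annotated))
        votes = w_matrix @ member[perm]  # targets x terms
        scores = (base * pi_vec[None, :] + votes) / z_vec[:, None]
        exceed += scores[rows, cols] >= obs - 1e-12
    pvals = (1.0 + exceed) / (params.n_perm + 1.0)

    out: list[FunScoreRecord] = []
    k = 0
    for r in candidates.records:
        if r.candidate:
            p_val = float(pvals[k])
            k += 1
            out.append(
                replace(
                    r,
                    p_value=p_val,
                    significant=p_val < P_SIGNIFICANT and r.score >= params.cutoff,
                )
            )
        else:
            out.append(replace(r))
    return FunScoreResult(out)
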