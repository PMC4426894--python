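"""Per-residue binding scores from cluster alignments.

Each surviving cluster contributes epsilon * C_R * C_B * C_D, where C_R is a
reciprocal-RMSD term (clusters at RMSD >= 3 A are rejected outright), C_B a
BLOSUM62 ratio and C_D a secondary-structure substitution ratio. A residue's
score is the maximum over all clusters containing it, across every template
of the database. The template's ligand-moiety center is back-projected into
query coordinates through the inverse representative transform; residues
whose predicted centers of *different* moieties fall 3-9 A apart reinforce
each other. Scores are z-normalized per query protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import DegenerateScoresError, UnknownSymbolError
from .fragment_align import ClusterAlignment, cluster_triplet_pairs
from .structure_io import ResidueUnit, THREE_TO_ONE
from .template_db import BindingTemplate, TemplateDatabase

logger = logging.getLogger(__name__)

#: 8-state DSSP label -> 3-state collapse used by the default SS matrix.
SS_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def collapse_ss(label: str) -> str:
    return SS_COLLAPSE.get(label, "-")


class SubstitutionMatrix:
    """Symmetric integer substitution matrix with a symbol alphabet."""

    def __init__(self, alphabet: list[str], scores: np.ndarray):
        self.alphabet = list(alphabet)
        self.scores = np.asarray(scores, dtype=int)
        if self.scores.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.alphabet)}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise UnknownSymbolError(f"symbol {exc.args[0]!r} not in matrix alphabet") from None

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionMatrix":
        """Parse a plain-text square matrix with a header row of symbols."""
        rows = [
            line.split()
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        alphabet = rows[0]
        scores = np.zeros((len(alphabet), len(alphabet)), dtype=int)
        for r, row in enumerate(rows[1:]):
            if row[0] != alphabet[r]:
                raise ValueError(
                    f"matrix row symbol {row[0]!r} does not match header {alphabet[r]!r}"
                )
            scores[r] = [int(x) for x in row[1:]]
        return cls(alphabet, scores)

    @classmethod
    def from_file(cls, path) -> "SubstitutionMatrix":
        from pathlib import Path

        return cls.from_text(Path(path).read_text())


def load_blosum62() -> SubstitutionMatrix:
    text = resources.files("fragsite.data").joinpath("blosum62.txt").read_text()
    return SubstitutionMatrix.from_text(text)


def load_ss_matrix() -> SubstitutionMatrix:
    text = resources.files("fragsite.data").joinpath("ss3_matrix.txt").read_text()
    return SubstitutionMatrix.from_text(text)


@dataclass
class ScoreComponents:
    """The factors of one cluster's contribution."""

    c_r: float
    c_b: float
    c_d: float
    epsilon: int

    @property
    def raw_product(self) -> float:
        return self.epsilon * self.c_r * self.c_b * self.c_d


@dataclass
class ResiduePrediction:
    """Final per-residue output of the scoring stage."""

    chain_id: str
    seq_pos: int | str
    res_name: str
    score: float
    moiety: str | None = None
    theta: np.ndarray | None = None
    best_template_id: str | None = None
    boosted_score: float | None = None
    z_score: float | None = None
    call: bool = False


@dataclass
class ScoringParams:
    d0: float = 2.0
    min_cluster_size: int = 2
    # pre-filter on the 3-atom superposition residual; 1.0 A keeps noisy but
    # genuine backbone matches while still discarding distorted geometry
    residual_max: float = 1.0
    rmsd_max: float = 3.0
    boost_lo: float = 3.0
    boost_hi: float = 9.0
    boost_mode: str = "sum"  # or "max_single"
    z_threshold: float = 1.645  # approx. 5% upper tail; evaluation overrides
    cluster_metric: str = "rmsd"
    symmetric_distance: bool = True
    refine_transform: bool = True
    blosum: SubstitutionMatrix = field(default_factory=load_blosum62)
    ss_matrix: SubstitutionMatrix = field(default_factory=load_ss_matrix)


# ---------------------------------------------------------------------------
# Score components
# ---------------------------------------------------------------------------

def rmsd_component(rmsd: float, rmsd_max: float = 3.0) -> float | None:
    """1 / (1 + RMSD), or None (cluster rejected) when RMSD >= rmsd_max."""
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if rmsd >= rmsd_max:
        return None
    return 1.0 / (1.0 + rmsd)


def blosum_component(
    aligned_pairs: list[tuple[str, str]], matrix: SubstitutionMatrix
) -> tuple[int, float]:
    """Sequence-similarity factor: sum of scores over aligned (query,
    template) one-letter pairs, divided by the template self-score plus one."""
    if not aligned_pairs:
        raise ValueError("no aligned pairs")
    raw = sum(matrix.score(q, t) for q, t in aligned_pairs)
    denom = sum(matrix.score(t, t) for _, t in aligned_pairs) + 1
    return raw, raw / denom


def dssp_component(
    aligned_pairs: list[tuple[str, str]], matrix: SubstitutionMatrix
) -> tuple[int, float]:
    """Secondary-structure factor, same ratio form as the sequence factor."""
    if not aligned_pairs:
        raise ValueError("no aligned pairs")
    raw = sum(matrix.score(q, t) for q, t in aligned_pairs)
    denom = sum(matrix.score(t, t) for _, t in aligned_pairs) + 1
    return raw, raw / denom


def score_cluster(
    cluster: ClusterAlignment,
    query_residues: list[ResidueUnit],
    template: BindingTemplate,
    params: ScoringParams,
) -> ScoreComponents | None:
    """Composite components for one cluster; None if the RMSD filter rejects it."""
    c_r = rmsd_component(cluster.rmsd_ca, params.rmsd_max)
    if c_r is None:
        return None
    t_names = template.res_names()
    t_ss = template.ss_labels()
    seq_pairs = []
    ss_pairs = []
    for p in cluster.pairs:
        q = query_residues[p.query_index]
        q1 = q.one_letter
        if q1 is None:
            raise UnknownSymbolError(f"residue {q.res_name!r} has no one-letter code")
        t1 = THREE_TO_ONE.get(t_names[p.template_index])
        if t1 is None:
            raise UnknownSymbolError(
                f"template residue {t_names[p.template_index]!r} has no one-letter code"
            )
        seq_pairs.append((q1, t1))
        ss_pairs.append((collapse_ss(q.ss_label), collapse_ss(t_ss[p.template_index])))
    _, c_b = blosum_component(seq_pairs, params.blosum)
    _, c_d = dssp_component(ss_pairs, params.ss_matrix)
    return ScoreComponents(c_r=c_r, c_b=c_b, c_d=c_d, epsilon=cluster.epsilon)


# ---------------------------------------------------------------------------
# Per-residue scoring
# ---------------------------------------------------------------------------

def residue_binding_scores(
    query_chain: list[ResidueUnit],
    db: TemplateDatabase,
    params: ScoringParams | None = None,
    exclude_sources: set[str] | None = None,
) -> list[ResiduePrediction]:
    """Score every residue of one query chain against a template database.

    A residue's score is the maximum epsilon * C_R * C_B * C_D over all
    surviving clusters (from all templates) containing its triplet; residues
    in no cluster score 0. Templates whose source PDB id is in
    ``exclude_sources`` are skipped (leave-one-out).
    """
    params = params or ScoringParams()
    exclude_sources = {s.lower() for s in (exclude_sources or set())}

    alignable = [
        r for r in query_chain if r.triplet is not None and r.is_standard
    ]
    predictions = {
        r.seq_pos: ResiduePrediction(
            chain_id=r.chain_id, seq_pos=r.seq_pos, res_name=r.res_name, score=0.0
        )
        for r in query_chain
    }
    if not alignable or len(db) == 0:
        return [predictions[r.seq_pos] for r in query_chain]

    query_triplets = [r.triplet for r in alignable]
    for template in db.templates:
        if template.source_pdb.lower() in exclude_sources:
            continue
        clusters = cluster_triplet_pairs(
            query_triplets,
            template.triplets(),
            d0=params.d0,
            min_size=params.min_cluster_size,
            residual_max=params.residual_max,
            symmetric=params.symmetric_distance,
            metric=params.cluster_metric,
            refine_transform=params.refine_transform,
        )
        for cluster in clusters:
            comp = score_cluster(cluster, alignable, template, params)
            if comp is None:
                continue
            score = comp.raw_product
            theta = cluster.rep_transform.inverse().apply(template.ligand_center)
            for p in cluster.pairs:
                residue = alignable[p.query_index]
                pred = predictions[residue.seq_pos]
                if score > pred.score:
                    pred.score = score
                    pred.moiety = template.moiety
                    pred.theta = theta
                    pred.best_template_id = template.template_id
    out = []
    for r in query_chain:
        pred = predictions[r.seq_pos]
        if pred.score <= 0:
            pred.theta = None
            pred.moiety = None
            pred.best_template_id = None
            pred.score = max(pred.score, 0.0)
        out.append(pred)
    return out


def apply_moiety_boost(
    predictions: list[ResiduePrediction], params: ScoringParams | None = None
) -> list[ResiduePrediction]:
    """Cross-moiety reinforcement of binding scores.

    A residue's score is raised by the (pre-boost) score of every other
    positively scored residue whose predicted ligand center of a *different*
    moiety lies within [boost_lo, boost_hi] A of its own. Pre-boost values
    are snapshotted first, so the result is order-independent.
    """
    params = params or ScoringParams()
    base = [(p.score, p.moiety, p.theta) for p in predictions]
    for i, p in enumerate(predictions):
        s_i, w_i, th_i = base[i]
        if s_i <= 0 or th_i is None:
            p.boosted_score = max(s_i, 0.0)
            continue
        add = []
        for k, (s_k, w_k, th_k) in enumerate(base):
            if k == i or s_k <= 0 or th_k is None or w_k == w_i:
                continue
            dist = float(np.linalg.norm(np.asarray(th_i) - np.asarray(th_k)))
            if params.boost_lo <= dist <= params.boost_hi:
                add.append(s_k)
        if not add:
            p.boosted_score = s_i
        elif params.boost_mode == "sum":
            p.boosted_score = s_i + sum(add)
        elif params.boost_mode == "max_single":
            p.boosted_score = s_i + max(add)
        else:
            raise ValueError(f"unknown boost_mode {params.boost_mode!r}")
    return predictions


def normalize_scores(scores) -> np.ndarray:
    """Z-normalize scores of one query protein (sample SD, n - 1)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise DegenerateScoresError("need at least 2 residues to normalize")
    sd = float(np.std(scores, ddof=1))
    # scale-relative guard: identical values can leave a tiny nonzero SD
    if sd <= 1e-12 * max(1.0, float(np.abs(scores).max())):
        raise DegenerateScoresError("all binding scores identical (SD = 0)")
    return (scores - scores.mean()) / sd


def score_query(
    chains: dict[str, list[ResidueUnit]],
    db: TemplateDatabase,
    params: ScoringParams | None = None,
    exclude_sources: set[str] | None = None,
) -> list[ResiduePrediction]:
    """Full scoring pipeline for one query protein (all chains pooled).

    Raw scores, cross-moiety boost, then z-normalization and the binary
    call over all residues of the protein. Degenerate proteins (constant
    scores) get z = 0 everywhere and no positive calls.
    """
    params = params or ScoringParams()
    predictions: list[ResiduePrediction] = []
    for chain in chains.values():
        predictions.extend(residue_binding_scores(chain, db, params, exclude_sources))
    apply_moiety_boost(predictions, params)
    boosted = [p.boosted_score for p in predictions]
    try:
        z = normalize_scores(boosted)
    except DegenerateScoresError:
        logger.warning("degenerate score distribution; all calls negative")
        z = np.zeros(len(predictions))
        for p in predictions:
            p.z_score = 0.0
            p.call = False
        return predictions
    for p, zi in zip(predictions, z):
        p.z_score = float(zi)
        p.call = bool(zi >= params.z_threshold)
    return predictions


def predictions_to_frame(predictions: list[ResiduePrediction]):
    """Predictions as a pandas DataFrame (the prediction TSV layout)."""
    import pandas as pd

    rows = []
    for p in predictions:
        theta = p.theta if p.theta is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "chain": p.chain_id,
                "seq_pos": p.seq_pos,
                "res_name": p.res_name,
                "moiety": p.moiety or "",
                "C_raw": p.score,
                "C_boosted": p.boosted_score if p.boosted_score is not None else p.score,
                "Z": p.z_score if p.z_score is not None else np.nan,
                "call": p.call,
                "theta_x": theta[0],
                "theta_y": theta[1],
                "theta_z": theta[2],
                "best_template_id": p.best_template_id or "",
            }
        )
    return pd.DataFrame(rows)
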