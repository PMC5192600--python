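"""Ensemble gene-regulatory-network inference (PLSNET).

The p-gene inference problem is decomposed into p per-target subproblems:
for each target gene the remaining eligible regulators form the candidate
feature set, and PLS-based feature selection (``plsnet.pls``) scores how
strongly each candidate explains the target's expression.  To stabilise
the scores against the unknown number of true regulators, each subproblem
is solved T times on a random resample of the conditions and a random
subset of K candidate regulators; the VIP a gene receives is summed over
the iterations in which it was sampled.

Per-target score vectors fill the *columns* of the adjacency matrix W
(rows are regulators, columns targets).  A final refinement multiplies
each regulator row by its sample variance: a hub regulator that strongly
drives some targets and not others has an elevated row variance, so its
edges are promoted in the global ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .exceptions import DimensionError, ValidationError
from .pls import _simpls_vip

__all__ = [
    "ScoreMatrix",
    "PLSNET",
    "default_n_candidates",
    "infer_target",
    "infer_network",
    "refine_network",
    "rank_edges",
]

# Below this gene count the DREAM4-style default K = 30 applies; above it
# the large-network default K = round(sqrt(p)) takes over.
SMALL_NETWORK_P = 200


def default_n_candidates(p: int) -> int:
    """Default candidate-subset size: 30 for small networks, round(sqrt(p))
    for large ones."""
    return 30 if p <= SMALL_NETWORK_P else max(1, round(math.sqrt(p)))


@dataclass
class ScoreMatrix:
    """Nonnegative p x p adjacency-score matrix.

    ``values[i, j]`` is the inferred strength that gene ``gene_ids[i]``
    regulates gene ``gene_ids[j]``.  The diagonal is structurally zero and
    rows of genes outside the regulator set (when one was supplied) are
    all zero.  ``refined`` guards against applying the hub-variance
    refinement twice.
    """

    values: np.ndarray
    gene_ids: tuple
    regulators: tuple | None = None
    refined: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = tuple(self.gene_ids)
        if self.regulators is not None:
            self.regulators = tuple(self.regulators)
        p = len(self.gene_ids)
        if self.values.shape != (p, p):
            raise ValidationError(
                f"score matrix shape {self.values.shape} does not match "
                f"{p} gene ids"
            )
        if len(set(self.gene_ids)) != p:
            raise ValidationError("gene ids must be unique")
        if np.any(self.values < 0):
            raise ValidationError("score matrix entries must be nonnegative")
        if np.any(np.diagonal(self.values) != 0):
            raise ValidationError("score matrix diagonal must be zero")
        if self.regulators is not None:
            unknown = set(self.regulators) - set(self.gene_ids)
            if unknown:
                raise ValidationError(f"unknown regulator ids: {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        """Regulator-by-target DataFrame view."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def _resolve_genes(data):
    """Accept a DataFrame (gene ids from columns) or a bare 2-D array."""
    if isinstance(data, pd.DataFrame):
        values = data.to_numpy(dtype=float)
        gene_ids = tuple(str(c) for c in data.columns)
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim != 2:
            raise DimensionError("expression data must be 2-D")
        gene_ids = tuple(f"G{i + 1}" for i in range(values.shape[1]))
    n, p = values.shape
    if n < 3 or p < 2:
        raise ValidationError(
            f"need at least 3 conditions and 2 genes, got shape {values.shape}"
        )
    if len(set(gene_ids)) != p:
        raise ValidationError("gene ids must be unique")
    if not np.all(np.isfinite(values)):
        raise ValidationError("expression matrix contains missing/non-finite values")
    return values, gene_ids


def _draw_rows(rng, n, resample, subsample_fraction):
    if resample == "bootstrap":
        return rng.integers(0, n, size=n)
    if resample == "subsample":
        k = max(2, int(round(subsample_fraction * n)))
        return rng.choice(n, size=min(k, n), replace=False)
    if resample == "none":
        return None
    raise ValueError(f"unknown resample scheme: {resample!r}")


def _target_scores(
    X,
    target_idx,
    eligible,
    n_components,
    n_candidates,
    n_iterations,
    seed_seq,
    resample,
    subsample_fraction,
    scale,
):
    """Accumulated VIP scores for one target gene.

    Returns ``(scores, n_degenerate, work_units)`` where ``scores`` has one
    entry per gene (zero for the target itself and for genes never
    sampled), ``n_degenerate`` counts iterations whose fit carried no
    response information, and ``work_units`` tallies m_eff * n_rows * k
    per iteration for complexity accounting.
    """
    rng = np.random.default_rng(seed_seq)
    n, p = X.shape
    acc = np.zeros(p)
    k = min(n_candidates, eligible.size)
    n_degenerate = 0
    work_units = 0
    y_full = X[:, target_idx]
    for _ in range(n_iterations):
        if k < eligible.size:
            cand = rng.choice(eligible, size=k, replace=False)
        else:
            cand = eligible
        rows = _draw_rows(rng, n, resample, subsample_fraction)
        if rows is None:
            Xb = X[:, cand]
            yb = y_full
        else:
            Xb = X[np.ix_(rows, cand)]
            yb = y_full[rows]
        Xb = Xb - Xb.mean(axis=0)
        yb = yb - yb.mean()
        if scale:
            sd = Xb.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xb = Xb / sd
        m_eff = min(n_components, cand.size, Xb.shape[0] - 1)
        work_units += m_eff * Xb.shape[0] * cand.size
        vip = _simpls_vip(Xb, yb, m_eff)
        if vip is None:
            n_degenerate += 1
        else:
            acc[cand] += vip
    return acc, n_degenerate, work_units


class PLSNET(BaseEstimator):
    """PLS-based ensemble network inference.

    Fits one feature-selection subproblem per target gene, aggregating VIP
    scores over randomized resamples and candidate-regulator subsets, and
    refines the resulting adjacency matrix by regulator-row variance.

    Parameters
    ----------
    n_components : int, default=5
        PLS components per fit (clamped per iteration to the candidate
        count and resample size).
    n_candidates : int or None, default=None
        Candidate regulators K sampled per iteration.  ``None`` resolves
        to 30 when p <= 200 and round(sqrt(p)) otherwise.
    n_iterations : int, default=1000
        Ensemble iterations T per target.
    regulators : sequence of str or None, default=None
        Gene ids allowed as predictors (e.g. a transcription-factor list).
        ``None`` allows every gene.
    resample : {"bootstrap", "subsample", "none"}, default="bootstrap"
        Condition resampling per iteration: bootstrap draws n rows with
        replacement; subsample draws ``subsample_fraction * n`` rows
        without replacement; none uses all rows.
    subsample_fraction : float, default=0.8
        Row fraction for ``resample="subsample"``.
    scale_columns : bool, default=False
        Scale candidate columns to unit variance within each iteration
        (columns are always re-centered per resample).
    refine : bool, default=True
        Apply the hub-variance row refinement to the aggregated matrix.
    random_state : int or None, default=None
        Master seed.  Per-target substreams are spawned by target index,
        so results are independent of scheduling order and ``n_jobs``.
    n_jobs : int, default=1
        Parallel workers over targets (threads).

    Attributes
    ----------
    scores_ : (p, p) ndarray
        Final adjacency scores, rows = regulators, columns = targets
        (refined when ``refine=True``).
    raw_scores_ : (p, p) ndarray
        Aggregated VIP sums before refinement.
    gene_ids_ : tuple of str
    diagnostics_ : dict
        Per-target degenerate-iteration counts, keyed by gene id.
    work_units_ : int
        Accumulated m_eff * rows * candidates over all iterations; scales
        linearly in T, K and n.

    Examples
    --------
    >>> from plsnet.simulate import generate_network, simulate_expression
    >>> net = generate_network(p=10, avg_out_degree=2, seed=0)
    >>> expr = simulate_expression(net, n_conditions=50)
    >>> model = PLSNET(n_iterations=50, random_state=0).fit(expr)
    >>> model.scores_.shape
    (10, 10)
    """

    def __init__(
        self,
        n_components=5,
        n_candidates=None,
        n_iterations=1000,
        regulators=None,
        resample="bootstrap",
        subsample_fraction=0.8,
        scale_columns=False,
        refine=True,
        random_state=None,
        n_jobs=1,
    ):
        self.n_components = n_components
        self.n_candidates = n_candidates
        self.n_iterations = n_iterations
        self.regulators = regulators
        self.resample = resample
        self.subsample_fraction = subsample_fraction
        self.scale_columns = scale_columns
        self.refine = refine
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _validate(self, gene_ids):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_candidates is not None and self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.regulators is None:
            return None
        regs = [str(r) for r in self.regulators]
        if not regs:
            raise ValidationError("regulator list must be nonempty when given")
        unknown = set(regs) - set(gene_ids)
        if unknown:
            raise ValidationError(
                f"regulators not present in expression data: {sorted(unknown)}"
            )
        return regs

    def fit(self, X, y=None):
        values, gene_ids = _resolve_genes(X)
        regs = self._validate(gene_ids)
        n, p = values.shape
        k = self.n_candidates if self.n_candidates is not None else default_n_candidates(p)

        if regs is None:
            reg_idx = np.arange(p)
        else:
            index = {g: i for i, g in enumerate(gene_ids)}
            reg_idx = np.asarray(sorted(index[r] for r in regs))

        # one child stream per target, spawned up-front by target index
        children = np.random.SeedSequence(self.random_state).spawn(p)

        def run(j):
            eligible = reg_idx[reg_idx != j]
            if eligible.size == 0:
                # a target that is itself the only allowed regulator has no
                # candidates; its column stays zero
                if regs is not None:
                    return np.zeros(p), self.n_iterations, 0
                raise ValidationError(
                    f"target {gene_ids[j]!r} has no eligible candidate regulators"
                )
            return _target_scores(
                values,
                j,
                eligible,
                self.n_components,
                k,
                self.n_iterations,
                children[j],
                self.resample,
                self.subsample_fraction,
                self.scale_columns,
            )

        results = Parallel(n_jobs=self.n_jobs, prefer="threads")(
            delayed(run)(j) for j in range(p)
        )

        W = np.zeros((p, p))
        diagnostics = {}
        work = 0
        for j, (col, n_degenerate, work_units) in enumerate(results):
            W[:, j] = col
            diagnostics[gene_ids[j]] = n_degenerate
            work += work_units

        self.gene_ids_ = gene_ids
        self.regulators_ = tuple(regs) if regs is not None else None
        self.n_candidates_ = k
        self.raw_scores_ = W
        self.diagnostics_ = diagnostics
        self.work_units_ = int(work)
        if self.refine:
            self.scores_ = refine_network(self._as_score_matrix(W, refined=False)).values
        else:
            self.scores_ = W.copy()
        return self

    def _as_score_matrix(self, values, refined):
        return ScoreMatrix(
            values=values,
            gene_ids=self.gene_ids_,
            regulators=self.regulators_,
            refined=refined,
        )

    def score_matrix(self) -> ScoreMatrix:
        """The final :class:`ScoreMatrix` (refined when ``refine=True``)."""
        return self._as_score_matrix(self.scores_, refined=self.refine)

    def rank_edges(self, top_n=None) -> pd.DataFrame:
        """Ranked edge list from the fitted score matrix."""
        return rank_edges(self.score_matrix(), top_n=top_n)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def infer_target(data, target, **config) -> pd.Series:
    """Score every gene as a potential regulator of one target gene.

    Parameters are those of :class:`PLSNET`; returns a Series indexed by
    gene id (the target's own score is 0).
    """
    values, gene_ids = _resolve_genes(data)
    if target not in gene_ids:
        raise ValidationError(f"target {target!r} not among gene ids")
    est = PLSNET(**config)
    regs = est._validate(gene_ids)
    p = len(gene_ids)
    j = gene_ids.index(target)
    k = est.n_candidates if est.n_candidates is not None else default_n_candidates(p)
    if regs is None:
        reg_idx = np.arange(p)
    else:
        index = {g: i for i, g in enumerate(gene_ids)}
        reg_idx = np.asarray(sorted(index[r] for r in regs))
    eligible = reg_idx[reg_idx != j]
    if eligible.size == 0:
        raise ValidationError(f"target {target!r} has no eligible candidate regulators")
    children = np.random.SeedSequence(est.random_state).spawn(p)
    scores, _, _ = _target_scores(
        values,
        j,
        eligible,
        est.n_components,
        k,
        est.n_iterations,
        children[j],
        est.resample,
        est.subsample_fraction,
        est.scale_columns,
    )
    return pd.Series(scores, index=gene_ids, name=target)


def infer_network(data, **config) -> ScoreMatrix:
    """Run the full ensemble over every target; returns the refined
    :class:`ScoreMatrix` (pass ``refine=False`` for the raw aggregate)."""
    return PLSNET(**config).fit(data).score_matrix()


def refine_network(raw: ScoreMatrix) -> ScoreMatrix:
    """Hub-variance refinement: multiply each regulator row by its sample
    variance (ddof=1 over the full row, structural zeros included).

    Constant rows (zero variance) map to zero rows.  Refinement is not
    idempotent, so a matrix that is already refined is rejected.
    """
    if raw.refined:
        raise ValidationError("score matrix is already refined; refusing to re-apply")
    row_var = raw.values.var(axis=1, ddof=1)
    return ScoreMatrix(
        values=raw.values * row_var[:, None],
        gene_ids=raw.gene_ids,
        regulators=raw.regulators,
        refined=True,
    )


def rank_edges(scores: ScoreMatrix, top_n=None) -> pd.DataFrame:
    """All admissible (regulator, target) pairs sorted by descending score.

    Ties break by ascending regulator id then ascending target id, giving
    a total deterministic order.  Self-edges are excluded; when the score
    matrix carries a regulator set, only those rows are admissible.

    Returns a DataFrame with columns ``regulator``, ``target``, ``score``.
    """
    if top_n is not None and top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    ids = scores.gene_ids
    if scores.regulators is not None:
        reg_ids = set(scores.regulators)
        rows = [i for i, g in enumerate(ids) if g in reg_ids]
    else:
        rows = range(len(ids))
    records = [
        (ids[i], ids[j], scores.values[i, j])
        for i in rows
        for j in range(len(ids))
        if i != j
    ]
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    if top_n is not None:
        records = records[:top_n]
    return pd.DataFrame(records, columns=["regulator", "target", "score"])
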