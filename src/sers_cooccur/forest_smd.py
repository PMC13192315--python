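"""Random-forest classification with surrogate-split analysis.

A random forest is trained to separate spectral conditions; on top of the
fitted trees two quantities are computed that together turn the forest
into a feature-relation instrument:

* **Surrogate minimal depth (SMD).**  At every internal node, after the
  primary split is fixed, the best-mimicking splits on other variables
  (surrogate splits, CART convention with orientation flips) are recorded
  with their adjusted agreement.  A variable's depth in a tree is the
  minimal depth at which it appears as primary *or* surrogate; variables
  absent from a tree are penalized with the tree's deepest node depth + 1.
  The mean over trees is the SMD importance: low values mark variables
  that — directly or as stand-ins — drive early, informative splits.

* **Mean adjusted agreement (MAA).**  For a variable pair (i, j), the mean
  over all nodes with primary split i of the stored adjusted agreement of
  j (zero when j is not among the stored surrogates).  High MAA means j
  systematically partitions samples like i does: in spectra, a signature
  of band co-occurrence.

Tree growing itself (Gini impurity, bootstrap resampling, ``mtry`` random
candidate variables per split) is delegated to scikit-learn decision
trees; the surrogate recording, SMD scoring, permutation-null threshold
and MAA computation are implemented here.

Hyperparameters follow the conventions ``mtry = floor(p^(3/4))`` and
``s = max(1, floor(0.10 p))`` surrogate splits per node, where p is the
number of spectral variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import CountError, LabelError, SelectionError, StratificationError
from .spectra_io import SpectraSet, WavenumberAxis

__all__ = [
    "ForestParams",
    "Surrogate",
    "SplitNode",
    "SurrogateTree",
    "SurrogateForest",
    "SMDResult",
    "RelationMatrix",
    "compute_mtry",
    "compute_s",
    "split_train_test",
    "fit_forest",
    "adjusted_agreement",
    "surrogate_minimal_depth",
    "smd_threshold",
    "mean_adjusted_agreement",
    "maa_matrix",
    "pick_representatives",
    "predict",
    "evaluate",
    "oob_predictions",
    "EvalResult",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------


def compute_mtry(p: int) -> int:
    """Number of candidate variables per split: floor(p^(3/4)), clamped to [1, p]."""
    if p < 1:
        raise CountError("p must be >= 1")
    return int(min(max(np.floor(p**0.75), 1), p))


def compute_s(p: int) -> int:
    """Number of surrogate splits stored per node: max(1, floor(0.10 p))."""
    if p < 2:
        raise CountError("p must be >= 2")
    return int(max(1, np.floor(0.10 * p)))


@dataclass
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` and ``s`` default to the p-dependent formulas when left None.
    ``num_trees`` defaults to 1000 for desk-scale work; the study-scale
    value is 10000.  ``min_node_size`` is the minimal node size that may
    still be split.
    """

    num_trees: int = 1000
    mtry: int | None = None
    s: int | None = None
    min_node_size: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    p: int | None = None

    def resolve(self, p: int) -> "ForestParams":
        """Fill in p-dependent defaults and validate."""
        mtry = self.mtry if self.mtry is not None else compute_mtry(p)
        s = self.s if self.s is not None else compute_s(p)
        if not 1 <= mtry <= p:
            raise CountError(f"mtry={mtry} outside [1, {p}]")
        if not 1 <= s <= p - 1:
            raise CountError(f"s={s} outside [1, {p - 1}]")
        if not 0.0 < self.train_fraction < 1.0:
            raise CountError("train_fraction must lie in (0, 1)")
        if self.num_trees < 1 or self.min_node_size < 2:
            raise CountError("num_trees >= 1 and min_node_size >= 2 required")
        return replace(self, mtry=mtry, s=s, p=p)


# ---------------------------------------------------------------------------
# forest data structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Surrogate:
    """A stored surrogate split: variable, threshold, orientation, quality."""

    var: int
    threshold: float
    flipped: bool
    agreement: float  # adjusted agreement A, in (0, 1]


@dataclass
class SplitNode:
    """An internal tree node: primary split plus its surrogate list."""

    primary_var: int
    primary_threshold: float
    depth: int
    left_fraction: float
    surrogates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.left_fraction < 1.0:
            raise CountError("left_fraction must lie strictly in (0, 1)")
        seen = {self.primary_var}
        for sur in self.surrogates:
            if sur.var in seen:
                raise CountError("surrogate variables must be distinct from primary")
            if sur.agreement <= 0:
                raise CountError("stored surrogates must have positive agreement")
            seen.add(sur.var)


@dataclass
class SurrogateTree:
    """Internal nodes of one tree plus the depth of its deepest node."""

    nodes: list
    max_depth: int


@dataclass
class SurrogateForest:
    """A fitted forest with recorded surrogate splits."""

    trees: list
    params: ForestParams
    classes: np.ndarray
    estimators: list = field(default_factory=list, repr=False)
    bootstrap_indices: list = field(default_factory=list, repr=False)


@dataclass
class SMDResult:
    """Per-variable surrogate minimal depth with selection threshold."""

    smd: np.ndarray
    threshold: float
    selected: np.ndarray

    @classmethod
    def from_threshold(cls, smd: np.ndarray, threshold: float) -> "SMDResult":
        return cls(smd, threshold, smd < threshold)


@dataclass
class RelationMatrix:
    """MAA of representative variables against all spectral variables."""

    representatives: list
    maa: np.ndarray  # (len(representatives), p), entries in [0, 1]


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------


def split_train_test(
    sset: SpectraSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[SpectraSet, SpectraSet]:
    """Stratified random partition into train and test sets.

    Each class contributes ``round(train_fraction * n_class)`` spectra to
    the training set (clamped so both sides stay non-empty); the partition
    is disjoint, exhaustive, and deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(set(sset.labels)):
        rows = np.flatnonzero(sset.labels == cls)
        if rows.size < 2:
            raise StratificationError(f"class {cls!r} has fewer than 2 spectra")
        n_train = int(np.clip(round(train_fraction * rows.size), 1, rows.size - 1))
        perm = rng.permutation(rows)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        sset.subset(np.sort(np.concatenate(train_idx))),
        sset.subset(np.sort(np.concatenate(test_idx))),
    )


# ---------------------------------------------------------------------------
# surrogate-split search
# ---------------------------------------------------------------------------


def _surrogate_search_matrix(
    x_node: np.ndarray, left_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best mimicking cut per column of ``x_node``.

    Returns per-column arrays (agreement a, adjusted A, threshold, flipped).
    Columns with no valid cut (constant within the node) get A = -inf.
    Trivial cuts sending all samples to one side are not candidates; their
    agreement equals the baseline m = max(left_fraction, 1-left_fraction)
    by construction, so nothing above A = 0 is lost.
    """
    m, p = x_node.shape
    tot_left = int(left_mask.sum())
    baseline = max(tot_left, m - tot_left) / m
    order = np.argsort(x_node, axis=0, kind="stable")
    xs = np.take_along_axis(x_node, order, axis=0)
    ls = left_mask[order]
    cum_left = np.cumsum(ls, axis=0)
    k1 = np.arange(1, m + 1)[:, None]
    a_norm = (2 * cum_left - k1 + (m - tot_left)) / m  # low side -> left
    a_flip = (k1 - 2 * cum_left + tot_left) / m        # low side -> right
    valid = xs[:-1] < xs[1:]
    a_norm = np.where(valid, a_norm[:-1], -np.inf)
    a_flip = np.where(valid, a_flip[:-1], -np.inf)
    flipped = a_flip > a_norm
    a_best_by_cut = np.where(flipped, a_flip, a_norm)
    if a_best_by_cut.size == 0:
        a = np.full(p, -np.inf)
        return a, a, np.zeros(p), np.zeros(p, dtype=bool)
    best_cut = np.argmax(a_best_by_cut, axis=0)
    cols = np.arange(p)
    a = a_best_by_cut[best_cut, cols]
    thresholds = 0.5 * (xs[best_cut, cols] + xs[best_cut + 1, cols])
    adj = np.where(
        np.isfinite(a), (a - baseline) / max(1.0 - baseline, np.finfo(float).tiny), -np.inf
    )
    return a, adj, thresholds, flipped[best_cut, cols]


def adjusted_agreement(
    x_candidate: np.ndarray, left_mask: np.ndarray
) -> tuple[float, bool, float] | None:
    """Best surrogate cut of one candidate variable at a node.

    ``left_mask`` marks the samples the primary split sends left.  Returns
    ``(threshold, flipped, A)`` where A = (a - m) / (1 - m) is the adjusted
    agreement of the best cut (orientation flips allowed), or ``None`` when
    the candidate is constant within the node.  Only A > 0 qualifies a cut
    as a storable surrogate; the raw value is returned so callers can
    study the null distribution.
    """
    x_candidate = np.asarray(x_candidate, dtype=float)
    left_mask = np.asarray(left_mask, dtype=bool)
    if x_candidate.ndim != 1 or x_candidate.shape != left_mask.shape:
        raise CountError("candidate and mask must be 1-D and equally long")
    if left_mask.all() or not left_mask.any():
        raise CountError("primary split must send samples to both sides")
    _, adj, thr, flip = _surrogate_search_matrix(x_candidate[:, None], left_mask)
    if not np.isfinite(adj[0]):
        return None
    return float(thr[0]), bool(flip[0]), float(adj[0])


def _node_surrogates(
    x_node: np.ndarray, left_mask: np.ndarray, primary_var: int, s: int
) -> list:
    """Top-``s`` surrogates with positive adjusted agreement at one node."""
    _, adj, thresholds, flipped = _surrogate_search_matrix(x_node, left_mask)
    adj[primary_var] = -np.inf
    candidates = np.flatnonzero(adj > 0.0)
    if candidates.size == 0:
        return []
    # sort by adjusted agreement descending, ties toward lower variable index
    order = candidates[np.lexsort((candidates, -adj[candidates]))][:s]
    return [
        Surrogate(int(v), float(thresholds[v]), bool(flipped[v]), float(adj[v]))
        for v in order
    ]


# ---------------------------------------------------------------------------
# forest fitting
# ---------------------------------------------------------------------------


def _extract_tree(
    est: DecisionTreeClassifier, x_boot: np.ndarray, s: int, surrogates: bool
) -> SurrogateTree:
    tree = est.tree_
    nodes: list = []
    stack = [(0, 0, np.arange(x_boot.shape[0]))]
    max_depth = 0
    while stack:
        nid, depth, idx = stack.pop()
        max_depth = max(max_depth, depth)
        if tree.children_left[nid] == -1:
            continue
        f = int(tree.feature[nid])
        thr = float(tree.threshold[nid])
        mask = x_boot[idx, f] <= thr
        sur = _node_surrogates(x_boot[idx], mask, f, s) if surrogates else []
        nodes.append(SplitNode(f, thr, depth, float(mask.mean()), sur))
        stack.append((int(tree.children_left[nid]), depth + 1, idx[mask]))
        stack.append((int(tree.children_right[nid]), depth + 1, idx[~mask]))
    return SurrogateTree(nodes, max_depth)


def fit_forest(
    train: SpectraSet, params: ForestParams, surrogates: bool = True
) -> SurrogateForest:
    """Grow a classification forest and record surrogate splits.

    Trees are grown on bootstrap samples with ``mtry`` random candidate
    variables per split and Gini impurity.  When ``surrogates`` is true, up
    to ``s`` surrogate splits with positive adjusted agreement are searched
    exhaustively over all other variables at every internal node and
    stored.  The fit is deterministic for a fixed ``params.seed``.
    """
    classes = np.array(sorted(set(train.labels)))
    if classes.size < 2:
        raise LabelError("training set must contain at least two classes")
    params = params.resolve(train.p)
    x = train.matrix
    y = np.searchsorted(classes, train.labels.astype(str))
    rng = np.random.default_rng(params.seed)
    n = train.n
    trees, estimators, boots = [], [], []
    for _ in range(params.num_trees):
        boot = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        est = DecisionTreeClassifier(
            criterion="gini",
            max_features=params.mtry,
            min_samples_split=params.min_node_size,
            random_state=tree_seed,
        )
        x_boot = x[boot]
        est.fit(x_boot, y[boot])
        trees.append(_extract_tree(est, x_boot, params.s, surrogates))
        estimators.append(est)
        boots.append(boot)
    return SurrogateForest(trees, params, classes, estimators, boots)


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------


def _majority_vote(votes: np.ndarray) -> np.ndarray:
    """Row-wise argmax with ties broken toward the lower class index."""
    return np.argmax(votes, axis=1)


def predict(forest: SurrogateForest, matrix: np.ndarray) -> np.ndarray:
    """Majority-vote class labels for a matrix of spectra."""
    votes = np.zeros((matrix.shape[0], forest.classes.size))
    for est in forest.estimators:
        pred = est.predict(matrix).astype(int)
        votes[np.arange(matrix.shape[0]), pred] += 1
    return forest.classes[_majority_vote(votes)]


def oob_predictions(forest: SurrogateForest, train: SpectraSet) -> np.ndarray:
    """Out-of-bag majority-vote labels (object array; None if never OOB)."""
    n = train.n
    votes = np.zeros((n, forest.classes.size))
    for est, boot in zip(forest.estimators, forest.bootstrap_indices):
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        pred = est.predict(train.matrix[oob]).astype(int)
        votes[oob, pred] += 1
    out = np.full(n, None, dtype=object)
    covered = votes.sum(axis=1) > 0
    out[covered] = forest.classes[_majority_vote(votes[covered])]
    return out


@dataclass
class EvalResult:
    """Overall accuracy and per-class sensitivity of a prediction set."""

    accuracy: float
    sensitivity: dict
    n: int


def evaluate(forest: SurrogateForest, test: SpectraSet) -> EvalResult:
    """Held-out accuracy and per-class sensitivity (recall)."""
    if test.n < 1:
        raise CountError("empty test set")
    unknown = set(test.labels) - set(forest.classes)
    if unknown:
        raise LabelError(f"test labels outside training vocabulary: {unknown}")
    pred = predict(forest, test.matrix)
    correct = pred == test.labels.astype(str)
    sensitivity = {
        str(cls): float(correct[test.labels == cls].mean())
        for cls in forest.classes
        if (test.labels == cls).any()
    }
    return EvalResult(float(correct.mean()), sensitivity, test.n)


# ---------------------------------------------------------------------------
# SMD and MAA
# ---------------------------------------------------------------------------


def surrogate_minimal_depth(forest: SurrogateForest) -> np.ndarray:
    """Mean minimal depth of each variable as primary or surrogate split.

    Per tree, a variable's depth is the minimum depth of any node where it
    is the primary split or among the stored surrogates; a variable absent
    from a tree contributes the tree's deepest node depth + 1.
    """
    p = forest.params.p
    total = np.zeros(p)
    for tree in forest.trees:
        depth = np.full(p, float(tree.max_depth + 1))
        for node in tree.nodes:
            if node.depth < depth[node.primary_var]:
                depth[node.primary_var] = node.depth
            for sur in node.surrogates:
                if node.depth < depth[sur.var]:
                    depth[sur.var] = node.depth
        total += depth
    return total / len(forest.trees)


def smd_threshold(
    train: SpectraSet,
    params: ForestParams,
    n_null: int = 8,
    seed: int = 0,
    null_num_trees: int | None = None,
    percentile: float = 0.0,
) -> float:
    """Permutation-null selection threshold for SMD importance.

    Fits forests on label-permuted copies of the training set, pools their
    SMD values, and returns the ``percentile`` of the pool — by default the
    pooled minimum (percentile 0).  Spectral variables are strongly
    correlated with their axis neighbors, so under the null the SMD spread
    across variables is structural and does not shrink with more trees; a
    familywise-conservative threshold at the pooled minimum keeps the
    selection empty on label-permuted data, where a per-variable tail
    quantile would not.  Null forests may use fewer trees than the analysis
    forest (default ``num_trees // 8``, at least 25), which widens their
    lower tail and makes the threshold more conservative still; the
    reduction is logged.  Deterministic for a fixed seed.
    """
    if n_null < 1:
        raise CountError("n_null must be >= 1")
    params = params.resolve(train.p)
    if null_num_trees is None:
        null_num_trees = max(25, params.num_trees // 8)
    if null_num_trees != params.num_trees:
        logger.info(
            "permutation null uses %d trees per forest (analysis forest: %d)",
            null_num_trees,
            params.num_trees,
        )
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_null):
        perm = rng.permutation(train.n)
        permuted = SpectraSet(train.axis, train.matrix, train.labels[perm])
        null_params = replace(
            params, num_trees=null_num_trees, seed=int(rng.integers(0, 2**31 - 1))
        )
        null_forest = fit_forest(permuted, null_params, surrogates=True)
        pooled.append(surrogate_minimal_depth(null_forest))
    return float(np.percentile(np.concatenate(pooled), percentile))


def mean_adjusted_agreement(forest: SurrogateForest, i: int, j: int) -> float:
    """MAA(i, j): mean stored adjusted agreement of j at nodes with primary i.

    Nodes where j is not among the stored surrogates contribute zero.
    MAA(i, i) = 1 by convention; 0 when i is never a primary split.
    """
    if i == j:
        return 1.0
    total, count = 0.0, 0
    for tree in forest.trees:
        for node in tree.nodes:
            if node.primary_var != i:
                continue
            count += 1
            for sur in node.surrogates:
                if sur.var == j:
                    total += sur.agreement
                    break
    return total / count if count else 0.0


def _maa_row(forest: SurrogateForest, i: int) -> np.ndarray:
    p = forest.params.p
    total = np.zeros(p)
    count = 0
    for tree in forest.trees:
        for node in tree.nodes:
            if node.primary_var != i:
                continue
            count += 1
            for sur in node.surrogates:
                total[sur.var] += sur.agreement
    row = total / count if count else total
    row[i] = 1.0
    return row


def maa_matrix(forest: SurrogateForest, representatives: list) -> RelationMatrix:
    """MAA of each representative variable against all p variables."""
    if not representatives:
        raise SelectionError("no representative variables")
    maa = np.vstack([_maa_row(forest, int(i)) for i in representatives])
    return RelationMatrix(list(representatives), maa)


def pick_representatives(
    selected: np.ndarray,
    smd: np.ndarray,
    axis: WavenumberAxis | None = None,
    gap: int = 2,
) -> list:
    """One representative variable per contiguous selected signal.

    Selected variables within ``gap`` channels of each other belong to the
    same signal; within each group, the variable with the lowest SMD is the
    representative, ties broken toward the lower wavenumber.
    """
    selected = np.asarray(selected)
    if selected.dtype == bool:
        selected = np.flatnonzero(selected)
    if selected.size == 0:
        raise SelectionError("empty selection")
    selected = np.sort(selected)
    groups = [[int(selected[0])]]
    for v in selected[1:]:
        if v - groups[-1][-1] <= gap:
            groups[-1].append(int(v))
        else:
            groups.append([int(v)])
    reps = []
    for group in groups:
        vals = smd[group]
        reps.append(group[int(np.argmin(vals))])  # argmin takes first = lower index
    return reps
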