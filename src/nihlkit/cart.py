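"""Classification tree (CART) for gene-gene / gene-environment interaction.

Recursive binary partitioning of case-control subjects over genotype and
environmental predictors:

* splitting rule — information gain in bits (binary entropy impurity), with
  Gini as a configurable alternative;
* genotype variables offer the three level bipartitions {AA} vs {AB,BB},
  {BB} vs {AA,AB}, {AB} vs {AA,BB}; booleans one split; ordered numerics
  thresholds at midpoints of observed values (optionally restricted to fixed
  clinical cutpoints such as age 45 or CNE 95);
* growth stops at min node size, max depth, purity or zero gain; the grown
  tree is then pruned by cost-complexity pruning with k-fold cross-validated
  misclassification error (grow-then-prune, optional 1-SE rule);
* each terminal node's risk is a 2x2 odds ratio against the terminal node
  with the lowest case fraction (the reference node), optionally with a
  covariate-adjusted logistic counterpart.

Everything is deterministic under a fixed seed: tie-breaks follow variable
declaration order and partition enumeration order, node ids are preorder.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import OddsRatio, fit_logistic, odds_ratio_woolf
from .cohort import CASE, CONTROL, CohortTable, ContingencyTable2x2

log = logging.getLogger(__name__)

GENOTYPE_LEVELS = ("AA", "AB", "BB")


# --------------------------------------------------------------------------
# impurity
# --------------------------------------------------------------------------

def node_entropy(n_cases: int, n_controls: int) -> float:
    """Binary entropy of a node's class mix, in bits (0·log0 = 0)."""
    n = n_cases + n_controls
    if n <= 0:
        raise ValueError("empty node has no entropy")
    h = 0.0
    for count in (n_cases, n_controls):
        if count > 0:
            p = count / n
            h -= p * math.log2(p)
    return h


def node_gini(n_cases: int, n_controls: int) -> float:
    n = n_cases + n_controls
    if n <= 0:
        raise ValueError("empty node has no impurity")
    p = n_cases / n
    return 2.0 * p * (1.0 - p)


_IMPURITY: dict[str, Callable[[int, int], float]] = {
    "information": node_entropy,
    "gini": node_gini,
}


# --------------------------------------------------------------------------
# variables and candidate splits
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CartVariable:
    """A predictor offered to the tree.

    kind: "genotype" (levels AA/AB/BB), "binary" (False/True), or "numeric"
    (ordered).  ``cutpoints``, if given for a numeric variable, restricts the
    threshold search to those fixed clinical cutpoints.
    """

    name: str
    kind: str
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("genotype", "binary", "numeric"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class Split:
    """A binary partition of one variable's values.

    Categorical (genotype/binary): subjects whose value is in ``left_levels``
    go left.  Numeric: subjects with value < ``threshold`` go left.
    """

    variable: str
    kind: str
    left_levels: frozenset | None = None
    threshold: float | None = None

    def goes_left(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "numeric":
            return np.asarray(values, dtype=float) < self.threshold
        isin = np.isin(values, list(self.left_levels))
        return isin

    def describe(self, left: bool) -> str:
        if self.kind == "numeric":
            op = "<" if left else ">="
            return f"{self.variable} {op} {self.threshold:g}"
        levels = sorted(self.left_levels, key=str)
        if self.kind == "binary":
            val = levels[0] if left else ({False, True} - set(levels)).pop()
            return f"{self.variable} = {'yes' if val else 'no'}"
        if left:
            return f"{self.variable} in {{{'/'.join(map(str, levels))}}}"
        other = sorted(set(GENOTYPE_LEVELS) - set(levels))
        return f"{self.variable} in {{{'/'.join(other)}}}"


def candidate_splits(variable: CartVariable, values: np.ndarray) -> list[Split]:
    """Enumerate the binary partitions of one variable over observed values.

    Genotype: the three level-subset bipartitions (in the fixed order
    {AA}, {BB}, {AB} as the left singleton).  Binary: one split.  Numeric:
    midpoints of sorted unique values, or the configured cutpoints.
    A constant variable yields no splits.
    """
    if variable.kind == "genotype":
        present = set(np.asarray(values, dtype=object))
        out = []
        for level in ("AA", "BB", "AB"):
            left = frozenset({level})
            right = set(GENOTYPE_LEVELS) - {level}
            # keep only partitions that actually separate observed values
            if present & {level} and present & right:
                out.append(Split(variable.name, "genotype", left_levels=left))
        return out
    if variable.kind == "binary":
        vals = set(np.asarray(values).astype(bool).tolist())
        if len(vals) < 2:
            return []
        return [Split(variable.name, "binary", left_levels=frozenset({False}))]
    # numeric
    v = np.asarray(values, dtype=float)
    uniq = np.unique(v[np.isfinite(v)])
    if len(uniq) < 2:
        return []
    if variable.cutpoints is not None:
        thresholds = [t for t in variable.cutpoints if uniq[0] < t <= uniq[-1]]
    else:
        thresholds = ((uniq[:-1] + uniq[1:]) / 2.0).tolist()
    return [Split(variable.name, "numeric", threshold=float(t)) for t in thresholds]


# --------------------------------------------------------------------------
# design container
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CartFrame:
    """Predictor columns + binary outcome, with complete cases only."""

    X: pd.DataFrame
    y: np.ndarray  # bool, True = case
    variables: tuple[CartVariable, ...]

    @property
    def n(self) -> int:
        return len(self.y)


def cart_frame(
    cohort: CohortTable,
    snp_ids: Sequence[str],
    covariates: Sequence[str] = (),
    cutpoints: Mapping[str, Sequence[float]] | None = None,
) -> CartFrame:
    """Assemble the CART design from a cohort.

    Genotype columns keep their AA/AB/BB strings; boolean covariates become
    binary variables; other covariates numeric (with optional fixed
    cutpoints).  Rows with any missing predictor, and subjects that are
    neither case nor control, are dropped (complete-case tree fitting).
    """
    cutpoints = dict(cutpoints or {})
    status = cohort.subjects["status"]
    keep = status.isin([CASE, CONTROL])
    cols = {}
    variables = []
    for snp in snp_ids:
        cols[snp] = cohort.genotypes[snp]
        variables.append(CartVariable(snp, "genotype"))
    for cov in covariates:
        ser = cohort.subjects[cov]
        if ser.dtype == bool or str(ser.dtype) == "boolean":
            cols[cov] = ser.astype("boolean")
            variables.append(CartVariable(cov, "binary"))
        else:
            cols[cov] = pd.to_numeric(ser)
            cp = tuple(cutpoints[cov]) if cov in cutpoints else None
            variables.append(CartVariable(cov, "numeric", cutpoints=cp))
    X = pd.DataFrame(cols)[keep]
    complete = X.notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        log.info("cart_frame: dropped %d subjects with missing predictors", n_drop)
    X = X[complete]
    for cov in covariates:
        if isinstance(X[cov].dtype, pd.BooleanDtype):
            X[cov] = X[cov].astype(bool)
    y = (status[keep][complete] == CASE).to_numpy()
    return CartFrame(X=X, y=y, variables=tuple(variables))


# --------------------------------------------------------------------------
# split search
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CartConfig:
    learning_fraction: float = 0.65
    min_node_size: int = 20       # minimum subjects in each child (minbucket)
    min_split_gain: float = 0.0
    max_depth: int = 6
    cv_folds: int = 10
    impurity: str = "information"
    one_se_rule: bool = True  # pick the smallest tree within 1 SE of the CV minimum
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_fraction < 1:
            raise ValueError("learning_fraction must be in (0,1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.impurity not in _IMPURITY:
            raise ValueError(f"impurity must be one of {sorted(_IMPURITY)}")


def _weighted_child_impurity(y_left: np.ndarray, y_right: np.ndarray, impurity) -> float:
    nl, nr = len(y_left), len(y_right)
    hl = impurity(int(y_left.sum()), nl - int(y_left.sum()))
    hr = impurity(int(y_right.sum()), nr - int(y_right.sum()))
    return (nl * hl + nr * hr) / (nl + nr)


def best_split(
    frame: CartFrame,
    idx: np.ndarray,
    config: CartConfig,
) -> tuple[Split, float] | None:
    """Best binary split of the subjects in ``idx`` by impurity decrease.

    Maximizes parent impurity minus child-size-weighted mean impurity over
    all variables (declaration order) and candidate partitions (enumeration
    order); first-best wins on ties, so the search is deterministic.
    Returns None when no split clears ``min_split_gain`` with both children
    at least ``min_node_size`` subjects.
    """
    impurity = _IMPURITY[config.impurity]
    y = frame.y[idx]
    n = len(y)
    n_cases = int(y.sum())
    parent = impurity(n_cases, n - n_cases)
    if parent == 0.0 or n < 2 * config.min_node_size:
        return None
    best: tuple[Split, float] | None = None
    best_gain = config.min_split_gain
    for var in frame.variables:
        values = frame.X[var.name].to_numpy()[idx]
        if var.kind == "numeric" and var.cutpoints is None:
            found = _best_numeric_split(var, values, y, config, parent, impurity)
            if found is not None and found[1] > best_gain:
                best, best_gain = found, found[1]
            continue
        for split in candidate_splits(var, values):
            left = split.goes_left(values)
            nl = int(left.sum())
            if nl < config.min_node_size or n - nl < config.min_node_size:
                continue
            gain = parent - _weighted_child_impurity(y[left], y[~left], impurity)
            if gain > best_gain:
                best, best_gain = (split, gain), gain
    return best


def _best_numeric_split(var, values, y, config, parent, impurity):
    """Vectorized threshold scan for a free numeric variable.

    Reproduces the candidate_splits enumeration (midpoints of sorted unique
    values, ascending) with first-best tie-breaking.
    """
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order].astype(int)
    uniq, first_idx = np.unique(vs, return_index=True)
    if len(uniq) < 2:
        return None
    # prefix sums at boundaries between distinct values: after position
    # first_idx[i] - 1 everything below uniq[i] is left of the midpoint
    cum_cases = np.cumsum(ys)
    n = len(ys)
    total_cases = cum_cases[-1]
    boundary = first_idx[1:]  # size of left child for each midpoint
    nl = boundary.astype(int)
    cl = cum_cases[boundary - 1]
    nr = n - nl
    cr = total_cases - cl
    ok = (nl >= config.min_node_size) & (nr >= config.min_node_size)
    if not ok.any():
        return None
    if impurity is node_entropy:
        def h(cases, size):
            with np.errstate(divide="ignore", invalid="ignore"):
                p = cases / size
                out = np.zeros_like(p, dtype=float)
                for q in (p, 1 - p):
                    mask = q > 0
                    out[mask] -= q[mask] * np.log2(q[mask])
            return out
    else:
        def h(cases, size):
            p = cases / size
            return 2 * p * (1 - p)
    child = (nl * h(cl, nl) + nr * h(cr, nr)) / n
    gain = parent - child
    gain[~ok] = -np.inf
    i = int(np.argmax(gain))  # argmax returns the first (lowest threshold) max
    if gain[i] <= config.min_split_gain:
        return None
    threshold = float((uniq[i] + uniq[i + 1]) / 2.0)
    return Split(var.name, "numeric", threshold=threshold), float(gain[i])


# --------------------------------------------------------------------------
# tree growth
# --------------------------------------------------------------------------

@dataclasses.dataclass
class CartNode:
    node_id: int
    depth: int
    n_cases: int
    n_controls: int
    impurity: float
    split: Split | None = None
    left: "CartNode | None" = None
    right: "CartNode | None" = None

    @property
    def terminal(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n

    @property
    def majority_case(self) -> bool:
        # ties predict control
        return self.n_cases > self.n_controls


@dataclasses.dataclass
class CartTree:
    root: CartNode
    variables: tuple[CartVariable, ...]
    config: CartConfig

    def nodes(self) -> list[CartNode]:
        out: list[CartNode] = []

        def walk(node: CartNode) -> None:
            out.append(node)
            if not node.terminal:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def terminal_nodes(self) -> list[CartNode]:
        return [n for n in self.nodes() if n.terminal]

    def renumber(self) -> None:
        """Assign preorder node ids (deterministic)."""
        for i, node in enumerate(self.nodes()):
            node.node_id = i

    def route(self, row: Mapping) -> CartNode:
        """Route one subject to its terminal node.

        Raises KeyError/ValueError on a missing split variable.
        """
        node = self.root
        while not node.terminal:
            value = row[node.split.variable]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"missing value for split variable {node.split.variable!r}")
            left = bool(node.split.goes_left(np.asarray([value], dtype=object))[0]) \
                if node.split.kind != "numeric" else float(value) < node.split.threshold
            node = node.left if left else node.right
        return node

    def route_frame(self, X: pd.DataFrame) -> np.ndarray:
        """Terminal node id per row; -1 for unroutable rows."""
        out = np.full(len(X), -1, dtype=int)

        def walk(node: CartNode, mask: np.ndarray) -> None:
            if node.terminal:
                out[mask] = node.node_id
                return
            values = X[node.split.variable].to_numpy()
            if node.split.kind == "numeric":
                vals = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy()
                known = np.isfinite(vals)
                left = np.zeros(len(X), dtype=bool)
                left[known] = vals[known] < node.split.threshold
            else:
                known = ~pd.isna(values)
                left = np.zeros(len(X), dtype=bool)
                left[known] = np.isin(values[known], list(node.split.left_levels))
            walk(node.left, mask & known & left)
            walk(node.right, mask & known & ~left)
            out[mask & ~known] = -1

        walk(self.root, np.ones(len(X), dtype=bool))
        return out

    def node_predicates(self) -> dict[int, str]:
        """Terminal node id -> human-readable predicate conjunction."""
        out: dict[int, str] = {}

        def walk(node: CartNode, preds: list[str]) -> None:
            if node.terminal:
                out[node.node_id] = " AND ".join(preds) if preds else "(root)"
                return
            walk(node.left, preds + [node.split.describe(left=True)])
            walk(node.right, preds + [node.split.describe(left=False)])

        walk(self.root, [])
        return out

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: CartNode, indent: int, label: str) -> None:
            mix = f"{node.n_controls} ctrl / {node.n_cases} case"
            if node.terminal:
                lines.append(f"{'  ' * indent}{label}node {node.node_id} [terminal] {mix}")
            else:
                lines.append(
                    f"{'  ' * indent}{label}node {node.node_id} "
                    f"[split {node.split.describe(left=True)}] {mix}")
                walk(node.left, indent + 1, "L: ")
                walk(node.right, indent + 1, "R: ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def grow_tree(frame: CartFrame, config: CartConfig, idx: np.ndarray | None = None) -> CartTree:
    """Grow a tree by recursive best-split partitioning.

    Stops at max depth, purity, minimum node size, or no positive gain.
    Node ids are preorder.
    """
    if idx is None:
        idx = np.arange(frame.n)
    idx = np.asarray(idx)
    if len(idx) == 0:
        raise ValueError("empty learning set")
    impurity = _IMPURITY[config.impurity]

    def build(sub_idx: np.ndarray, depth: int) -> CartNode:
        y = frame.y[sub_idx]
        n_cases = int(y.sum())
        node = CartNode(node_id=-1, depth=depth, n_cases=n_cases,
                        n_controls=len(y) - n_cases,
                        impurity=impurity(n_cases, len(y) - n_cases))
        if depth >= config.max_depth:
            return node
        found = best_split(frame, sub_idx, config)
        if found is None:
            return node
        split, _gain = found
        values = frame.X[split.variable].to_numpy()[sub_idx]
        left = split.goes_left(values)
        node.split = split
        node.left = build(sub_idx[left], depth + 1)
        node.right = build(sub_idx[~left], depth + 1)
        return node

    tree = CartTree(root=build(idx, 0), variables=frame.variables, config=config)
    tree.renumber()
    return tree


# --------------------------------------------------------------------------
# learning/testing partition
# --------------------------------------------------------------------------

def partition_learning_testing(
    y_or_cohort,
    config: CartConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random split into learning/testing sets, stratified by status.

    Accepts a CohortTable or a boolean case indicator array.  Per stratum the
    learning-set size is round(fraction * n), so sizes are within 1 of the
    65/35 target.
    """
    if isinstance(y_or_cohort, CohortTable):
        status = y_or_cohort.subjects["status"]
        is_case = (status == CASE).to_numpy()
        eligible = status.isin([CASE, CONTROL]).to_numpy()
    else:
        is_case = np.asarray(y_or_cohort, dtype=bool)
        eligible = np.ones(len(is_case), dtype=bool)
    rng = np.random.default_rng(config.seed)
    learn_parts, test_parts = [], []
    for stratum in (True, False):
        pool = np.flatnonzero(eligible & (is_case == stratum))
        perm = rng.permutation(pool)
        n_learn = int(round(config.learning_fraction * len(pool)))
        learn_parts.append(perm[:n_learn])
        test_parts.append(perm[n_learn:])
    learning = np.sort(np.concatenate(learn_parts))
    testing = np.sort(np.concatenate(test_parts))
    return learning, testing


# --------------------------------------------------------------------------
# cost-complexity pruning with cross-validation
# --------------------------------------------------------------------------

def _resubstitution_error(node: CartNode) -> int:
    """Misclassified count at a node if it were terminal (majority vote)."""
    return min(node.n_cases, node.n_controls)


def _subtree_error_and_leaves(node: CartNode) -> tuple[int, int]:
    if node.terminal:
        return _resubstitution_error(node), 1
    el, ll = _subtree_error_and_leaves(node.left)
    er, lr = _subtree_error_and_leaves(node.right)
    return el + er, ll + lr


def _clone(node: CartNode) -> CartNode:
    new = CartNode(node_id=node.node_id, depth=node.depth, n_cases=node.n_cases,
                   n_controls=node.n_controls, impurity=node.impurity, split=node.split)
    if not node.terminal:
        new.left = _clone(node.left)
        new.right = _clone(node.right)
    return new


def _weakest_link_alphas(root: CartNode) -> list[float]:
    """The increasing alpha sequence of cost-complexity pruning."""
    alphas = []
    node = _clone(root)
    while not node.terminal:
        # find minimal g(t) = (R(t) - R(T_t)) / (leaves - 1) over internal nodes
        best_g, best_nodes = math.inf, []

        def visit(t: CartNode) -> None:
            nonlocal best_g, best_nodes
            if t.terminal:
                return
            err, leaves = _subtree_error_and_leaves(t)
            g = (_resubstitution_error(t) - err) / (leaves - 1)
            if g < best_g - 1e-12:
                best_g, best_nodes = g, [t]
            elif g <= best_g + 1e-12:
                best_nodes.append(t)
            visit(t.left)
            visit(t.right)

        visit(node)
        alphas.append(best_g)
        for t in best_nodes:  # collapse all weakest links at this alpha
            t.split = None
            t.left = None
            t.right = None
    return alphas


def prune_at(tree: CartTree, alpha: float) -> CartTree:
    """Prune a copy of the tree at complexity parameter alpha.

    Iteratively collapses every internal node whose weakest-link value
    g(t) <= alpha (within numerical tolerance).
    """
    root = _clone(tree.root)
    changed = True
    while changed:
        changed = False
        best_g, best_nodes = math.inf, []

        def visit(t: CartNode) -> None:
            nonlocal best_g, best_nodes
            if t.terminal:
                return
            err, leaves = _subtree_error_and_leaves(t)
            g = (_resubstitution_error(t) - err) / (leaves - 1)
            if g < best_g - 1e-12:
                best_g, best_nodes = g, [t]
            elif g <= best_g + 1e-12:
                best_nodes.append(t)
            visit(t.left)
            visit(t.right)

        visit(root)
        if best_nodes and best_g <= alpha + 1e-12:
            for t in best_nodes:
                t.split = None
                t.left = None
                t.right = None
            changed = True
    out = CartTree(root=root, variables=tree.variables, config=tree.config)
    out.renumber()
    return out


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for stratum in (True, False):
        pool = rng.permutation(np.flatnonzero(y == stratum))
        for i, ix in enumerate(pool):
            folds[i % k].append(int(ix))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _tree_test_error(tree: CartTree, frame: CartFrame, idx: np.ndarray) -> int:
    """Misclassification count of held-out subjects (majority-vote leaves)."""
    node_ids = tree.route_frame(frame.X.iloc[idx])
    majority = {n.node_id: n.majority_case for n in tree.terminal_nodes()}
    y = frame.y[idx]
    wrong = 0
    for yy, nid in zip(y, node_ids):
        pred = majority.get(int(nid), False)  # unroutable counted as control
        wrong += int(pred != bool(yy))
    return wrong


def cv_prune(
    tree: CartTree,
    frame: CartFrame,
    idx: np.ndarray | None = None,
    config: CartConfig | None = None,
) -> tuple[CartTree, pd.DataFrame]:
    """Cost-complexity pruning guided by k-fold cross-validation.

    Computes the weakest-link alpha sequence of the full tree, evaluates the
    cross-validated misclassification error of each candidate subtree size
    (geometric-mean alphas, as in classical CART), selects the alpha with
    minimal CV error (ties break toward the smaller tree; optional 1-SE
    rule), and prunes the full tree there.  Returns the pruned tree plus the
    CV error profile.
    """
    config = config or tree.config
    if idx is None:
        idx = np.arange(frame.n)
    idx = np.asarray(idx)
    alphas = _weakest_link_alphas(tree.root)
    if not alphas:
        return tree, pd.DataFrame({"alpha": [0.0], "cv_error": [np.nan], "n_leaves": [1]})
    # candidate alphas: 0, geometric means of successive weakest links, +inf cap
    seq = [0.0] + [float(a) for a in alphas]
    candidates = []
    for i in range(len(seq)):
        if i + 1 < len(seq):
            lo, hi = max(seq[i], 0.0), max(seq[i + 1], 0.0)
            candidates.append(math.sqrt((lo + 1e-12) * (hi + 1e-12)))
        else:
            candidates.append(seq[i] + 1.0)
    rng = np.random.default_rng(config.seed + 1)
    k = min(config.cv_folds, len(idx))
    folds = _stratified_folds(frame.y[idx], k, rng)
    errors = np.zeros(len(candidates))
    for fold in folds:
        test_idx = idx[fold]
        train_mask = np.ones(len(idx), dtype=bool)
        train_mask[fold] = False
        train_idx = idx[train_mask]
        fold_tree = grow_tree(frame, config, idx=train_idx)
        for j, alpha in enumerate(candidates):
            pruned = prune_at(fold_tree, alpha)
            errors[j] += _tree_test_error(pruned, frame, test_idx)
    n_total = len(idx)
    cv_err = errors / n_total
    # ties toward the larger alpha (smaller tree)
    best_err = cv_err.min()
    if config.one_se_rule:
        se = math.sqrt(best_err * (1 - best_err) / n_total)
        ok = np.flatnonzero(cv_err <= best_err + se)
    else:
        ok = np.flatnonzero(cv_err <= best_err + 1e-12)
    chosen = candidates[int(ok[-1])]
    pruned = prune_at(tree, chosen)
    profile = pd.DataFrame({
        "alpha": candidates,
        "cv_error": cv_err,
        "n_leaves": [len(prune_at(tree, a).terminal_nodes()) for a in candidates],
    })
    return pruned, profile


# --------------------------------------------------------------------------
# terminal-node risk estimation
# --------------------------------------------------------------------------

def node_risk_table(
    tree: CartTree,
    frame: CartFrame,
    idx: np.ndarray | None = None,
    reference: int | str = "lowest_case_fraction",
    adjust_for: Sequence[str] = (),
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-terminal-node odds ratios against the reference node.

    Subjects in ``idx`` (default: all) are routed to terminal nodes; the
    reference is the terminal node with the lowest case fraction (ties break
    toward the larger node), or an explicit node id.  Crude ORs are 2x2
    cross-products vs the reference; if ``adjust_for`` covariates are given
    (with a matching ``covariates`` frame), adjusted ORs come from a
    logistic fit on node-indicator dummies plus covariates.
    Unroutable subjects are excluded and counted in the log.
    """
    terminals = tree.terminal_nodes()
    if len(terminals) < 2:
        raise ValueError("tree has fewer than 2 terminal nodes; no comparison possible")
    if idx is None:
        idx = np.arange(frame.n)
    idx = np.asarray(idx)
    node_ids = tree.route_frame(frame.X.iloc[idx])
    unroutable = int((node_ids < 0).sum())
    if unroutable:
        log.info("node_risk_table: %d subjects unroutable (missing split values)", unroutable)
    routed = node_ids >= 0
    y = frame.y[idx][routed]
    nid = node_ids[routed]

    counts = {}
    for t in terminals:
        mask = nid == t.node_id
        counts[t.node_id] = (int((mask & y).sum()), int((mask & ~y).sum()))

    if reference == "lowest_case_fraction":
        def sort_key(t: CartNode):
            ca, co = counts[t.node_id]
            frac = ca / (ca + co) if (ca + co) else math.inf
            return (frac, -(ca + co))
        ref_id = min(terminals, key=sort_key).node_id
    else:
        ref_id = int(reference)
        if ref_id not in counts:
            raise ValueError(f"reference node {ref_id} is not a terminal node")
    ref_cases, ref_controls = counts[ref_id]

    predicates = tree.node_predicates()
    rows = []
    for t in terminals:
        ca, co = counts[t.node_id]
        if t.node_id == ref_id:
            orr = OddsRatio(1.0, np.nan, np.nan, np.nan)
        else:
            table = ContingencyTable2x2(ca, co, ref_cases, ref_controls)
            orr = odds_ratio_woolf(table)
        rows.append({
            "node_id": t.node_id,
            "combination": predicates[t.node_id],
            "n_controls": co,
            "n_cases": ca,
            "or": orr.value,
            "ci_low": orr.ci_low,
            "ci_high": orr.ci_high,
            "p": orr.p,
            "reference": t.node_id == ref_id,
        })
    out = pd.DataFrame(rows)

    if adjust_for:
        if covariates is None:
            raise ValueError("adjust_for given but no covariates frame")
        cov = covariates.iloc[idx][list(adjust_for)].reset_index(drop=True)[routed]
        design = pd.DataFrame(index=cov.index)
        for t in terminals:
            if t.node_id == ref_id:
                continue
            design[f"node_{t.node_id}"] = (nid == t.node_id).astype(float)
        for c in adjust_for:
            design[c] = pd.to_numeric(cov[c].reset_index(drop=True), errors="coerce")
        complete = design.notna().all(axis=1).to_numpy()
        try:
            fit = fit_logistic(y[complete], design[complete])
            ors = fit.odds_ratios()
            out["or_adjusted"] = [
                1.0 if r["node_id"] == ref_id
                else float(ors.loc[f"node_{r['node_id']}", "or"])
                for _, r in out.iterrows()
            ]
            out["p_adjusted"] = [
                np.nan if r["node_id"] == ref_id
                else float(ors.loc[f"node_{r['node_id']}", "p"])
                for _, r in out.iterrows()
            ]
        except ValueError as exc:
            log.warning("adjusted node ORs unavailable: %s", exc)
    return out
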