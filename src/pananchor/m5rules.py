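"""M5 model trees and rule extraction for predicting mapping error.

The accuracy filter needs a regressor that is piecewise linear in the
attributes and human-inspectable.  This module implements the M5 family:

* a **model tree** grown by recursive splitting that maximises the
  standard-deviation reduction ``SDR = sd(T) - sum |T_i|/|T| * sd(T_i)``,
  stopped when a node's spread falls below a fraction of the root's or the
  node is too small;
* linear models at every node, fitted by least squares with greedy
  backward elimination under the ``(n + v) / (n - v)`` complexity penalty
  (v = fitted parameters), so a model earns each coefficient it keeps;
* bottom-up **pruning** that replaces a subtree by its node model whenever
  the penalized node error is no worse than the subtree's;
* **smoothing** of leaf predictions along the leaf-to-root path
  (``p' = (n p_child + k p_parent) / (n + k)``, k = 15) — since every model
  is linear the smoothed leaf model is itself a single linear model;
* **rule extraction**: repeatedly build a tree on the instances not yet
  covered, convert the leaf covering the most instances into a rule
  (path conditions + smoothed leaf model), remove its instances, repeat.

The response is the distance between a tag's genetic and physical position
on a log10(d+1) scale; raw distances span 0 to ~1e10 under the global
position transform and would otherwise dominate least squares.  Selection
thresholds are applied after back-transforming to bp.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import AttributeVector, BoxCoxParams, boxcox_apply, boxcox_fit

log = logging.getLogger(__name__)

SMOOTHING_K = 15.0

# predicted-distance selection thresholds per model class (bp)
DEFAULT_THRESHOLDS = {"GJ": 100_000, "G": 50_000, "J": 100_000}


# --------------------------------------------------------------------------
# linear models
# --------------------------------------------------------------------------

@dataclass
class LinearModel:
    intercept: float
    coef: np.ndarray  # dense over all attributes; unused attrs are 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.coef + self.intercept

    def n_params(self) -> int:
        return 1 + int(np.count_nonzero(self.coef))


def _penalty(n: int, v: int) -> float:
    return (n + v) / (n - v) if n > v else 10.0


def _fit_ls(X: np.ndarray, y: np.ndarray, use: list[int]) -> LinearModel:
    n, k = X.shape
    coef = np.zeros(k)
    if not use or n < 2:
        return LinearModel(float(y.mean()) if n else 0.0, coef)
    A = np.column_stack([X[:, use], np.ones(n)])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    coef[use] = sol[:-1]
    return LinearModel(float(sol[-1]), coef)


def _fit_linear(X: np.ndarray, y: np.ndarray, candidates=None) -> LinearModel:
    """Sparse least squares: greedy forward selection under the M5 penalty.

    ``candidates`` restricts the attributes the model may use (M5 gives a
    node only the attributes tested in its subtree).  Starting from an
    intercept-only model, the attribute whose addition most reduces the
    penalized MAE is added until nothing improves or the model would use
    more than n/3 coefficients — small nodes therefore stay near-constant
    instead of interpolating with huge cancelling coefficients.
    """
    n, k = X.shape
    if candidates is None:
        candidates = range(k)
    pool = [j for j in candidates if X[:, j].std() > 0]

    def pen_mae(m: LinearModel) -> float:
        mae = float(np.abs(y - m.predict(X)).mean()) if n else 0.0
        return mae * _penalty(n, m.n_params())

    model = _fit_ls(X, y, [])
    best_err = pen_mae(model)
    used: list[int] = []
    while pool and len(used) + 1 <= n // 3:
        trials = [(pen_mae(m := _fit_ls(X, y, used + [j])), j, m) for j in pool]
        err, j, m = min(trials, key=lambda t: (t[0], t[1]))
        if err >= best_err:
            break
        best_err, model = err, m
        used.append(j)
        pool.remove(j)
    return model


# --------------------------------------------------------------------------
# model tree
# --------------------------------------------------------------------------

@dataclass
class _Node:
    idx: np.ndarray  # training-instance indices at this node
    sd: float
    model: LinearModel | None = None
    smoothed: LinearModel | None = None
    split_attr: int | None = None
    split_val: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return len(self.idx)


@dataclass
class ModelTree:
    root: _Node
    attr_names: list[str]
    min_leaf: int
    smoothing: bool = True
    y_min: float = -np.inf
    y_max: float = np.inf

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.split_attr] <= node.split_val else node.right
            m = node.smoothed if (self.smoothing and node.smoothed) else node.model
            out[i] = m.predict(row[None, :])[0]
        # like any tree model, never extrapolate beyond the seen response range
        return np.clip(out, self.y_min, self.y_max)

    def leaves(self) -> list[tuple[list[tuple[int, str, float]], _Node]]:
        """(path conditions, leaf) pairs; condition = (attr, op, value)."""
        found = []

        def walk(node, conds):
            if node.is_leaf:
                found.append((conds, node))
                return
            walk(node.left, conds + [(node.split_attr, "<=", node.split_val)])
            walk(node.right, conds + [(node.split_attr, ">", node.split_val)])

        walk(self.root, [])
        return found


def _sd(y: np.ndarray) -> float:
    return float(y.std()) if len(y) else 0.0


def _best_split(X, y, idx, min_leaf):
    """Maximal-SDR split with both children >= min_leaf; None if no valid split."""
    n = len(idx)
    sd_total = _sd(y[idx])
    best = None  # (sdr, attr, threshold, left_idx, right_idx)
    for a in range(X.shape[1]):
        vals = X[idx, a]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[idx][order]
        c1 = np.cumsum(sy)
        c2 = np.cumsum(sy * sy)
        i = np.arange(min_leaf, n - min_leaf + 1)  # left sizes
        if len(i) == 0:
            continue
        valid = sv[i - 1] < sv[i]
        if not valid.any():
            continue
        i = i[valid]
        nl, nr = i.astype(float), (n - i).astype(float)
        sl = np.sqrt(np.maximum(c2[i - 1] / nl - (c1[i - 1] / nl) ** 2, 0.0))
        sr = np.sqrt(np.maximum((c2[-1] - c2[i - 1]) / nr - ((c1[-1] - c1[i - 1]) / nr) ** 2, 0.0))
        sdr = sd_total - (nl / n) * sl - (nr / n) * sr
        j = int(np.argmax(sdr))
        if best is None or sdr[j] > best[0] + 1e-15:
            thr = 0.5 * (sv[i[j] - 1] + sv[i[j]])
            left = idx[order[: i[j]]]
            right = idx[order[i[j] :]]
            best = (float(sdr[j]), a, float(thr), left, right)
    if best is None or best[0] <= 0:
        return None
    return best


def build_model_tree(
    X: np.ndarray,
    y: np.ndarray,
    attr_names: list[str] | None = None,
    min_leaf: int = 4,
    sd_stop_fraction: float = 0.05,
    smoothing: bool = True,
) -> ModelTree:
    """Grow, prune and smooth an M5 model tree.

    With fewer than ``2 * min_leaf`` instances the tree is a single global
    linear model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if attr_names is None:
        attr_names = [f"a{j}" for j in range(X.shape[1])]
    root_sd = _sd(y)
    sd_floor = sd_stop_fraction * root_sd

    def grow(idx) -> _Node:
        node = _Node(idx=idx, sd=_sd(y[idx]))
        if node.n < 2 * min_leaf or node.sd < sd_floor or node.sd == 0.0:
            return node
        split = _best_split(X, y, idx, min_leaf)
        if split is None:
            return node
        _, a, thr, li, ri = split
        node.split_attr, node.split_val = a, thr
        node.left, node.right = grow(li), grow(ri)
        return node

    root = grow(np.arange(len(y)))

    def subtree_attrs(node) -> set[int]:
        if node.is_leaf:
            return set()
        return {node.split_attr} | subtree_attrs(node.left) | subtree_attrs(node.right)

    def fit_and_prune(node) -> tuple[float, int]:
        """Bottom-up pruning; returns (raw training MAE, subtree parameter count).

        The subtree's penalized error charges every parameter it spent —
        each leaf model's coefficients plus two per split (attribute and
        threshold) — which counteracts the split-selection optimism of
        SDR-chosen children; without it, noise-chasing splits always look
        better than the node's own linear model on training error.
        """
        node.model = _fit_linear(X[node.idx], y[node.idx], sorted(subtree_attrs(node)))
        own = float(np.abs(y[node.idx] - node.model.predict(X[node.idx])).mean())
        own_pen = own * _penalty(node.n, node.model.n_params())
        if node.is_leaf:
            return own, node.model.n_params()
        le, lv = fit_and_prune(node.left)
        re_, rv = fit_and_prune(node.right)
        sub_raw = (node.left.n * le + node.right.n * re_) / node.n
        sub_v = lv + rv + 2
        if own_pen <= sub_raw * _penalty(node.n, sub_v):
            node.left = node.right = None
            node.split_attr = node.split_val = None
            return own, node.model.n_params()
        return sub_raw, sub_v

    fit_and_prune(root)

    def smooth(node, parent_model):
        if parent_model is None:
            mixed = node.model
        else:
            w = node.n / (node.n + SMOOTHING_K)
            mixed = LinearModel(
                w * node.model.intercept + (1 - w) * parent_model.intercept,
                w * node.model.coef + (1 - w) * parent_model.coef,
            )
        node.smoothed = mixed
        if not node.is_leaf:
            smooth(node.left, mixed)
            smooth(node.right, mixed)

    smooth(root, None)
    return ModelTree(
        root, list(attr_names), min_leaf, smoothing,
        float(y.min()) if len(y) else -np.inf,
        float(y.max()) if len(y) else np.inf,
    )


# --------------------------------------------------------------------------
# rules
# --------------------------------------------------------------------------

@dataclass
class Rule:
    conditions: list[tuple[int, str, float]]  # (attr index, "<=" | ">", value)
    model: LinearModel
    coverage: int

    def matches(self, x: np.ndarray) -> bool:
        for a, op, v in self.conditions:
            if op == "<=":
                if not x[a] <= v:
                    return False
            elif not x[a] > v:
                return False
        return True

    def matches_matrix(self, X: np.ndarray) -> np.ndarray:
        ok = np.ones(len(X), dtype=bool)
        for a, op, v in self.conditions:
            ok &= (X[:, a] <= v) if op == "<=" else (X[:, a] > v)
        return ok


@dataclass
class RuleModel:
    """Ordered first-match rule list with a global default model.

    Predicts log10(distance + 1); ``predict_distance`` back-transforms to bp.
    Carries the Box–Cox parameters the attributes were normalised with, so
    prediction on raw attribute vectors is self-contained.
    """

    model_class: str  # G | J | GJ
    attr_names: list[str]
    rules: list[Rule]
    default_model: LinearModel
    boxcox: BoxCoxParams
    training_r2: float = float("nan")
    training_mae: float = float("nan")
    y_min: float = -np.inf
    y_max: float = np.inf

    def predict_transformed(self, X: np.ndarray) -> np.ndarray:
        """Prediction on already-Box-Cox-transformed attribute rows."""
        X = np.atleast_2d(X)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            for rule in self.rules:
                if rule.matches(row):
                    out[i] = rule.model.predict(row[None, :])[0]
                    break
            else:
                out[i] = self.default_model.predict(row[None, :])[0]
        return np.clip(out, self.y_min, self.y_max)

    def predict_raw(self, values: np.ndarray) -> np.ndarray:
        X = boxcox_apply(self.boxcox, np.atleast_2d(values))
        return self.predict_transformed(X)


def extract_rules(
    X: np.ndarray,
    y: np.ndarray,
    attr_names: list[str] | None = None,
    min_leaf: int = 4,
    sd_stop_fraction: float = 0.05,
    smoothing: bool = True,
    max_rules: int | None = None,
    rule_choice: str = "coverage",
) -> tuple[list[Rule], LinearModel]:
    """M5Rules iteration: tree -> best leaf -> rule -> drop covered -> repeat.

    ``rule_choice`` picks the leaf by maximum coverage (default) or lowest
    training error ("error").  Returns the ordered rules plus a global
    default model fitted on all instances.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if attr_names is None:
        attr_names = [f"a{j}" for j in range(X.shape[1])]
    default = _fit_linear(X, y)
    remaining = np.arange(len(y))
    rules: list[Rule] = []
    while len(remaining) and (max_rules is None or len(rules) < max_rules):
        tree = build_model_tree(
            X[remaining], y[remaining], attr_names, min_leaf, sd_stop_fraction, smoothing
        )
        leaves = tree.leaves()
        if rule_choice == "coverage":
            conds, leaf = max(leaves, key=lambda cl: (cl[1].n, -len(cl[0])))
        else:
            def leaf_err(cl):
                node = cl[1]
                m = node.smoothed if smoothing else node.model
                resid = y[remaining][node.idx] - m.predict(X[remaining][node.idx])
                return float(np.abs(resid).mean())
            conds, leaf = min(leaves, key=leaf_err)
        model = leaf.smoothed if smoothing else leaf.model
        rule = Rule(conds, model, leaf.n)
        rules.append(rule)
        covered = rule.matches_matrix(X[remaining])
        if not covered.any():  # safety: cannot happen for a leaf of this tree
            break
        remaining = remaining[~covered]
    return rules, default


MIN_LEAF_GRID = (4, 8, 16, 32, 64)


def _cv_min_leaf(X, y, attr_names, sd_stop_fraction, smoothing, max_rules) -> int:
    """Pick min_leaf by deterministic 5-fold CV (interleaved folds) on MSE."""
    n = len(y)
    folds = np.arange(n) % 5
    best = (np.inf, MIN_LEAF_GRID[0])
    for ml in MIN_LEAF_GRID:
        if n < 4 * ml:
            continue
        sse = 0.0
        for f in range(5):
            tr, te = folds != f, folds == f
            rules, default = extract_rules(
                X[tr], y[tr], attr_names, ml, sd_stop_fraction, smoothing, max_rules
            )
            m = RuleModel("G", attr_names, rules, default,
                          BoxCoxParams([], np.empty(0), np.empty(0), np.empty(0), np.empty(0)),
                          y_min=float(y[tr].min()), y_max=float(y[tr].max()))
            sse += float(((y[te] - m.predict_transformed(X[te])) ** 2).sum())
        if sse < best[0]:
            best = (sse, ml)
    return best[1]


def train_accuracy_model(
    attributes: np.ndarray,
    distances_bp: np.ndarray,
    model_class: str,
    attr_names: list[str],
    min_leaf: int | None = None,
    sd_stop_fraction: float = 0.05,
    smoothing: bool = True,
    max_rules: int | None = None,
) -> RuleModel:
    """Train a rule model on uniquely-aligned reference tags.

    ``attributes`` are raw (untransformed) vectors; ``distances_bp`` the
    observed |genetic - physical| global-position distances.  Requires at
    least 100 instances.  ``min_leaf=None`` (the default) selects the leaf
    size by deterministic 5-fold cross-validation on the training set —
    at a few hundred instances the literature default of 4 chases noise.
    """
    attributes = np.asarray(attributes, dtype=np.float64)
    distances_bp = np.asarray(distances_bp, dtype=np.float64)
    if len(attributes) < 100:
        raise ValueError(
            f"insufficient training data: {len(attributes)} instances (< 100)"
        )
    if model_class not in DEFAULT_THRESHOLDS:
        raise ValueError(f"unknown model class {model_class!r}")
    bc = boxcox_fit(attributes, attr_names)
    X = boxcox_apply(bc, attributes)
    y = np.log10(distances_bp + 1.0)
    if min_leaf is None:
        min_leaf = _cv_min_leaf(X, y, attr_names, sd_stop_fraction, smoothing, max_rules)
        log.info("cross-validated min_leaf = %d", min_leaf)
    rules, default = extract_rules(
        X, y, attr_names, min_leaf, sd_stop_fraction, smoothing, max_rules
    )
    model = RuleModel(
        model_class, list(attr_names), rules, default, bc,
        y_min=float(y.min()), y_max=float(y.max()),
    )
    pred = model.predict_transformed(X)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    model.training_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    model.training_mae = float(np.abs(y - pred).mean())
    log.info(
        "trained M5Rules_%s: %d rules, training r2=%.3f, MAE=%.3f (log10 bp)",
        model_class, len(rules), model.training_r2, model.training_mae,
    )
    return model


def predict_distance(model: RuleModel, attrs: AttributeVector) -> float:
    """Predicted |genetic - physical| distance in bp (floored at 0)."""
    if attrs.model_class != model.model_class:
        raise ValueError(
            f"attribute class {attrs.model_class} does not match model class {model.model_class}"
        )
    yhat = float(model.predict_raw(attrs.values)[0])
    return max(0.0, 10.0**yhat - 1.0)


def select_anchors(
    candidates: list[tuple[object, str, float]],
    thresholds: dict[str, float] | None = None,
) -> list[tuple[object, str, float]]:
    """Keep (item, model_class, predicted_bp) entries with prediction <= class threshold."""
    thr = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    kept = []
    for item, cls, pred in candidates:
        if cls not in thr:
            raise ValueError(f"unknown model class {cls!r}")
        if pred <= thr[cls]:
            kept.append((item, cls, pred))
    return kept


# --------------------------------------------------------------------------
# persistence (human-readable text)
# --------------------------------------------------------------------------

def _fmt_model(m: LinearModel, names: list[str]) -> str:
    terms = [repr(float(m.intercept))]
    for j in np.flatnonzero(m.coef):
        terms.append(f"{float(m.coef[j])!r}*{names[j]}")
    return " + ".join(terms)


def _parse_model(text: str, names: list[str]) -> LinearModel:
    coef = np.zeros(len(names))
    intercept = 0.0
    for term in text.split(" + "):
        if "*" in term:
            c, name = term.split("*")
            coef[names.index(name)] = float(c)
        else:
            intercept = float(term)
    return LinearModel(intercept, coef)


def save_rule_model(model: RuleModel, path: str | Path) -> None:
    lines = [
        "# pananchor M5Rules model",
        f"class: {model.model_class}",
        "attributes: " + "\t".join(model.attr_names),
        f"training_r2: {float(model.training_r2)!r}",
        f"training_mae: {float(model.training_mae)!r}",
        f"y_range: {float(model.y_min)!r}\t{float(model.y_max)!r}",
        "[boxcox]",
        *model.boxcox.to_lines(),
        "[rules]",
    ]
    for i, rule in enumerate(model.rules, 1):
        conds = " AND ".join(
            f"{model.attr_names[a]} {op} {v!r}" for a, op, v in rule.conditions
        ) or "TRUE"
        lines.append(
            f"RULE {i} (coverage {rule.coverage}): {conds} -> y = "
            + _fmt_model(rule.model, model.attr_names)
        )
    lines.append("DEFAULT: y = " + _fmt_model(model.default_model, model.attr_names))
    Path(path).write_text("\n".join(lines) + "\n")


_RULE_RE = re.compile(r"RULE \d+ \(coverage (\d+)\): (.*) -> y = (.*)")


def load_rule_model(path: str | Path) -> RuleModel:
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    while not lines[i].startswith("[boxcox]"):
        if ":" in lines[i] and not lines[i].startswith("#"):
            k, _, v = lines[i].partition(":")
            header[k.strip()] = v.strip()
        i += 1
    names = header["attributes"].split("\t")
    i += 1
    bc_lines = []
    while not lines[i].startswith("[rules]"):
        bc_lines.append(lines[i])
        i += 1
    bc = BoxCoxParams.from_lines(bc_lines)
    rules: list[Rule] = []
    default = None
    for line in lines[i + 1 :]:
        m = _RULE_RE.match(line)
        if m:
            cov, cond_text, model_text = m.groups()
            conds = []
            if cond_text != "TRUE":
                for c in cond_text.split(" AND "):
                    name, op, val = c.rsplit(" ", 2)[0], c.split(" ")[-2], c.split(" ")[-1]
                    conds.append((names.index(name), op, float(val)))
            rules.append(Rule(conds, _parse_model(model_text, names), int(cov)))
        elif line.startswith("DEFAULT: y = "):
            default = _parse_model(line[len("DEFAULT: y = ") :], names)
    y_lo, y_hi = (
        header["y_range"].split("\t") if "y_range" in header else ("-inf", "inf")
    )
    return RuleModel(
        header["class"], names, rules, default, bc,
        float(header["training_r2"]), float(header["training_mae"]),
        float(y_lo), float(y_hi),
    )
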