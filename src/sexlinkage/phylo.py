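"""Mk-model inference and sex-chromosome turnover statistics.

Discrete sex-chromosome states (chromosome identities) evolve on a
dated, rooted, ultrametric tree (branch lengths in Myr) under a
K-state continuous-time Markov (Mk) model.  Tip data enter as a
probability matrix: a species with an uncertain or polymorphic state
gets a row spreading mass over the compatible states, a species with
no information gets the uniform row.

The module provides

* Felsenstein-pruning log-likelihood with per-branch matrix
  exponentials (:func:`mk_loglik`);
* maximum-likelihood fitting of ER / SYM / ARD rate constraints with
  AIC comparison (:func:`fit_mk`, :func:`compare_mk_models`);
* stochastic character mapping: full histories sampled conditionally
  on tip data, via conditional node sampling plus endpoint-conditioned
  CTMC path simulation (rejection sampling with a uniformization
  fallback) (:func:`stochastic_map`);
* turnover counting from mapped histories (consensus state change per
  branch) or from a curated event table (:func:`count_turnovers`);
* the turnover rate per Myr of independent evolution
  (:func:`turnover_rate`);
* exact binomial tests on heterogamety preservation
  (:func:`heterogamety_binomial`);
* the gene-resampling recruitment null and the recruitment-vs-gene-count
  regression (:func:`recruitment_null_test`,
  :func:`recruitment_regression`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import expm

from sexlinkage.simulate import label_internal_nodes, validate_rate_matrix

logger = logging.getLogger(__name__)

CONSTRAINTS = ("ER", "SYM", "ARD")
DEFAULT_STATES = ("Chr01", "Chr02", "Chr03", "Chr05", "Chr08")
RATE_BOUNDS = (1e-8, 1e3)  # per Myr


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def validate_dated_tree(tree: dendropy.Tree, tol: float = 1e-6) -> float:
    """Check rootedness/ultrametricity and return the root age (Myr)."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    depths = np.asarray(depths)
    if depths.size < 2:
        raise ValueError("tree needs at least two tips")
    if np.ptp(depths) > tol:
        raise ValueError(f"tree is not ultrametric within {tol} (spread {np.ptp(depths):.3g})")
    return float(depths.mean())


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.length))


@dataclass
class TipStateMatrix:
    """Per-tip probability rows over K named states."""

    states: tuple[str, ...]
    labels: np.ndarray
    probs: np.ndarray  # (n_tips, K)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.labels = np.asarray(self.labels, dtype=object)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.labels), len(self.states)):
            raise ValueError("probs shape does not match labels/states")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("tip probability rows must sum to 1")
        if (self.probs < 0).any():
            raise ValueError("tip probabilities must be >= 0")

    @property
    def K(self) -> int:
        return len(self.states)

    def row_for(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.labels == label)
        if idx.size != 1:
            raise KeyError(f"tip {label!r} not found exactly once in tip-state matrix")
        return self.probs[idx[0]]

    @classmethod
    def from_states(
        cls,
        tip_states: dict[str, int | str | None],
        states: tuple[str, ...] = DEFAULT_STATES,
    ) -> "TipStateMatrix":
        """Build from certain/unknown tip states; ``None`` (unknown)
        becomes the uniform row, a set/list spreads mass equally."""
        K = len(states)
        labels, rows = [], []
        index = {s: i for i, s in enumerate(states)}
        for label, st in tip_states.items():
            row = np.zeros(K)
            if st is None:
                row[:] = 1.0 / K
            elif isinstance(st, (set, frozenset, list, tuple)):
                for s in st:
                    row[index[s] if isinstance(s, str) else int(s)] = 1.0
                row /= row.sum()
            else:
                row[index[st] if isinstance(st, str) else int(st)] = 1.0
            labels.append(label)
            rows.append(row)
        return cls(tuple(states), np.array(labels, dtype=object), np.array(rows))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.probs, columns=list(self.states))
        df.insert(0, "tip", self.labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TipStateMatrix":
        df = pd.read_csv(path, sep="\t")
        states = tuple(df.columns[1:])
        return cls(states, df.iloc[:, 0].to_numpy(dtype=object), df.iloc[:, 1:].to_numpy(dtype=float))


def n_free_rates(K: int, constraint: str) -> int:
    if constraint == "ER":
        return 1
    if constraint == "SYM":
        return K * (K - 1) // 2
    if constraint == "ARD":
        return K * (K - 1)
    raise ValueError(f"unknown constraint {constraint!r}")


def build_rate_matrix(K: int, constraint: str, rates: np.ndarray) -> np.ndarray:
    """Generator matrix from the free-rate vector under a constraint.

    Free-rate ordering: ER a single scalar; SYM pairs (i<j) in row-major
    order; ARD ordered pairs (i, j), i != j, in row-major order.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size != n_free_rates(K, constraint):
        raise ValueError(f"{constraint} with K={K} needs {n_free_rates(K, constraint)} rates, got {rates.size}")
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    Q = np.zeros((K, K))
    if constraint == "ER":
        Q[:] = rates[0]
    elif constraint == "SYM":
        k = 0
        for i in range(K):
            for j in range(i + 1, K):
                Q[i, j] = Q[j, i] = rates[k]
                k += 1
    else:
        k = 0
        for i in range(K):
            for j in range(K):
                if i != j:
                    Q[i, j] = rates[k]
                    k += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class MkModel:
    """A K-state Mk model: constraint, free rates, root prior."""

    states: tuple[str, ...]
    constraint: str
    rates: np.ndarray
    root_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}")
        self.rates = np.asarray(self.rates, dtype=float)
        if self.root_prior is None:
            self.root_prior = np.full(self.K, 1.0 / self.K)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if not np.isclose(self.root_prior.sum(), 1.0):
            raise ValueError("root prior must sum to 1")
        self.Q = validate_rate_matrix(build_rate_matrix(self.K, self.constraint, self.rates))

    @property
    def K(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return n_free_rates(self.K, self.constraint)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _branch_transition_matrices(tree: dendropy.Tree, Q: np.ndarray) -> dict:
    P = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        M = expm(Q * t)
        # numerical guard: a proper stochastic matrix within 1e-10
        M = np.clip(M, 0.0, None)
        rowsum = M.sum(axis=1, keepdims=True)
        if np.abs(rowsum - 1.0).max() > 1e-10:
            raise FloatingPointError("matrix exponential rows deviate from 1 beyond 1e-10")
        P[node] = M / rowsum
    return P


def _partials(tree: dendropy.Tree, tips: TipStateMatrix, P: dict) -> tuple[dict, float]:
    """Downward (Felsenstein) pass.  Returns per-node partial
    likelihood vectors (rescaled) and the accumulated log-scale."""
    K = tips.K
    L: dict = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            # a probability row marks the states compatible with the tip;
            # it enters as a partial likelihood scaled to max 1, so a
            # fully unknown tip contributes likelihood 1, not 1/K
            row = tips.row_for(node.taxon.label).astype(float)
            L[node] = row / row.max()
        else:
            v = np.ones(K)
            for child in node.child_nodes():
                v = v * (P[child] @ L[child])
            s = v.max()
            if s <= 0:
                raise FloatingPointError("zero partial likelihood (data impossible under model)")
            L[node] = v / s
            log_scale += np.log(s)
    return L, log_scale


def mk_loglik(tree: dendropy.Tree, tips: TipStateMatrix, model: MkModel) -> float:
    """Log-likelihood of the tip data under the Mk model (pruning)."""
    _check_tip_labels(tree, tips)
    P = _branch_transition_matrices(tree, model.Q)
    L, log_scale = _partials(tree, tips, P)
    root = tree.seed_node
    lik = float(model.root_prior @ L[root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def _check_tip_labels(tree: dendropy.Tree, tips: TipStateMatrix) -> None:
    tree_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    matrix_labels = set(tips.labels)
    if not tree_labels <= matrix_labels:
        raise ValueError(f"tips missing from state matrix: {sorted(tree_labels - matrix_labels)}")


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class MkFit:
    model: MkModel
    lnL: float
    aic: float
    converged: bool


def fit_mk(
    tree: dendropy.Tree,
    tips: TipStateMatrix,
    constraint: str = "ER",
    n_starts: int = 10,
    root_prior: np.ndarray | None = None,
) -> MkFit:
    """Maximum-likelihood Mk fit under a rate constraint.

    Rates are optimised on the log scale with L-BFGS-B from
    ``n_starts`` log-spaced starting points within ``RATE_BOUNDS``;
    non-convergence is flagged and the best point returned.
    AIC = 2p - 2 lnL with p free rates.
    """
    p = n_free_rates(tips.K, constraint)
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def nll(log_rates: np.ndarray) -> float:
        model = MkModel(tips.states, constraint, np.exp(log_rates), root_prior)
        ll = mk_loglik(tree, tips, model)
        return 1e10 if not np.isfinite(ll) else -ll

    starts = np.log(np.geomspace(1e-4, 10.0, n_starts))
    best, best_val, any_converged = None, np.inf, False
    for s in starts:
        x0 = np.full(p, s)
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * p)
        if res.fun < best_val:
            best, best_val = res, res.fun
        any_converged = any_converged or bool(res.success)
    if not any_converged:
        logger.warning("Mk optimisation (%s) did not report convergence; returning best point", constraint)
    model = MkModel(tips.states, constraint, np.exp(best.x), root_prior)
    lnL = -best_val
    return MkFit(model, lnL, 2.0 * p - 2.0 * lnL, any_converged)


def compare_mk_models(
    tree: dendropy.Tree,
    tips: TipStateMatrix,
    constraints: tuple[str, ...] = CONSTRAINTS,
    n_starts: int = 10,
) -> pd.DataFrame:
    """Fit each constraint and tabulate lnL / AIC (lowest AIC first)."""
    rows = []
    fits = {}
    for c in constraints:
        fit = fit_mk(tree, tips, c, n_starts=n_starts)
        fits[c] = fit
        rows.append({"constraint": c, "n_params": fit.model.n_params, "lnL": fit.lnL, "AIC": fit.aic})
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df.attrs["fits"] = fits
    return df


def er_profile_interval(
    tree: dendropy.Tree,
    tips: TipStateMatrix,
    fit: MkFit,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the single ER rate."""
    if fit.model.constraint != "ER":
        raise ValueError("profile interval implemented for ER fits")
    crit = stats.chi2.ppf(level, df=1) / 2.0
    r_hat = float(fit.model.rates[0])
    target = fit.lnL - crit

    def deficit(log_r: float) -> float:
        model = MkModel(tips.states, "ER", [np.exp(log_r)], fit.model.root_prior)
        return mk_loglik(tree, tips, model) - target

    lo_bound, hi_bound = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    log_r_hat = np.log(max(r_hat, RATE_BOUNDS[0]))
    lower = RATE_BOUNDS[0] if deficit(lo_bound) >= 0 else np.exp(optimize.brentq(deficit, lo_bound, log_r_hat, xtol=1e-10))
    upper = RATE_BOUNDS[1] if deficit(hi_bound) >= 0 else np.exp(optimize.brentq(deficit, log_r_hat, hi_bound, xtol=1e-10))
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# stochastic mapping
# ---------------------------------------------------------------------------


@dataclass
class SimmapHistory:
    """One sampled character history: a state per node (tips included)
    and the ordered transition events along each branch."""

    node_states: dict[str, int]
    events: list[dict]  # branch, time, from_state, to_state

    def n_events(self) -> int:
        return len(self.events)


def _node_key(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _sample_path_rejection(Q, i, j, t, rng, max_attempts=100):
    """Endpoint-conditioned CTMC path by rejection (forward simulation;
    when i != j the first jump is forced via a truncated exponential)."""
    K = Q.shape[0]
    for _ in range(max_attempts):
        events = []
        state, tau = i, 0.0
        if i != j:
            rate = -Q[i, i]
            if rate <= 0:
                return None
            # first jump time conditioned on at least one jump in (0, t)
            u = rng.random()
            tau = -np.log(1.0 - u * (1.0 - np.exp(-rate * t))) / rate
            probs = np.clip(Q[i], 0.0, None)
            probs[i] = 0.0
            state = int(rng.choice(K, p=probs / probs.sum()))
            events.append({"time": tau, "from_state": i, "to_state": state})
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            tau = tau + rng.exponential(1.0 / rate)
            if tau >= t:
                break
            probs = np.clip(Q[state], 0.0, None)
            probs[state] = 0.0
            new = int(rng.choice(K, p=probs / probs.sum()))
            events.append({"time": tau, "from_state": state, "to_state": new})
            state = new
        if state == j:
            return events
    return None


def _sample_path_uniformization(Q, P_t, i, j, t, rng, max_jumps=1000):
    """Endpoint-conditioned path via uniformization: sample the number
    of (possibly virtual) jumps, then the bridge of states."""
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return []
    K = Q.shape[0]
    R = np.eye(K) + Q / mu
    # R powers as needed
    R_pows = [np.eye(K), R]
    p_ab = P_t[i, j]
    u = rng.random() * p_ab
    log_pois = -mu * t
    cum, n = 0.0, -1
    while cum < u and n < max_jumps:
        n += 1
        while len(R_pows) <= n:
            R_pows.append(R_pows[-1] @ R)
        pois_n = np.exp(log_pois + n * np.log(max(mu * t, 1e-300)) - _log_factorial(n))
        cum += pois_n * R_pows[n][i, j]
    if n <= 0:
        return []
    while len(R_pows) <= n:
        R_pows.append(R_pows[-1] @ R)
    times = np.sort(rng.random(n)) * t
    states = [i]
    for k in range(1, n):
        back = R_pows[n - k][:, j]
        w = np.clip(R[states[-1]] * back, 0.0, None)
        states.append(int(rng.choice(K, p=w / w.sum())))
    states.append(j)
    events = []
    for k in range(1, n + 1):
        if states[k] != states[k - 1]:
            events.append({"time": float(times[k - 1]), "from_state": states[k - 1], "to_state": states[k]})
    return events


def _log_factorial(n: int) -> float:
    from scipy.special import gammaln

    return float(gammaln(n + 1))


def stochastic_map(
    tree: dendropy.Tree,
    tips: TipStateMatrix,
    model: MkModel,
    n_maps: int = 1000,
    seed: int = 0,
    max_rejects: int = 100,
) -> list[SimmapHistory]:
    """Sample ``n_maps`` full character histories conditional on tips.

    Node states (tips included) are drawn from their conditional
    distributions via the pruning pass followed by root-to-tip
    sampling; branch histories by endpoint-conditioned CTMC simulation
    (rejection with a uniformization fallback, the fallback use is
    logged)."""
    _check_tip_labels(tree, tips)
    label_internal_nodes(tree)
    rng = np.random.default_rng(seed)
    Q = model.Q
    P = _branch_transition_matrices(tree, Q)
    L, _ = _partials(tree, tips, P)
    root = tree.seed_node
    n_fallback = 0

    histories: list[SimmapHistory] = []
    for _ in range(n_maps):
        node_state: dict = {}
        w = model.root_prior * L[root]
        node_state[root] = int(rng.choice(model.K, p=w / w.sum()))
        events: list[dict] = []
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            i = node_state[node.parent_node]
            w = P[node][i] * L[node]
            j = int(rng.choice(model.K, p=w / w.sum()))
            node_state[node] = j
            t = node.edge.length or 0.0
            if t > 0:
                path = _sample_path_rejection(Q, i, j, t, rng, max_attempts=max_rejects)
                if path is None:
                    n_fallback += 1
                    path = _sample_path_uniformization(Q, P[node], i, j, t, rng)
                branch = _node_key(node)
                for ev in path:
                    ev = dict(ev, branch=branch)
                    events.append(ev)
            elif i != j:
                raise FloatingPointError("state change required on zero-length branch")
        histories.append(SimmapHistory({_node_key(n): s for n, s in node_state.items()}, events))
    if n_fallback:
        logger.info("uniformization fallback used for %d branch paths", n_fallback)
    return histories


def branch_segments(history: SimmapHistory, tree: dendropy.Tree) -> dict[str, list[tuple[int, float]]]:
    """Ordered (state, duration) segments per branch, rootward first.

    Segment durations sum to the branch length and consecutive
    segment states differ.
    """
    events_by_branch: dict[str, list[dict]] = {}
    for ev in history.events:
        events_by_branch.setdefault(ev["branch"], []).append(ev)
    out: dict[str, list[tuple[int, float]]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        key = _node_key(node)
        blen = node.edge.length or 0.0
        state = history.node_states[_node_key(node.parent_node)]
        segments, prev_t = [], 0.0
        for ev in sorted(events_by_branch.get(key, []), key=lambda e: e["time"]):
            segments.append((state, ev["time"] - prev_t))
            state, prev_t = ev["to_state"], ev["time"]
        segments.append((state, blen - prev_t))
        out[key] = segments
    return out


def write_simmap(history: SimmapHistory, tree: dendropy.Tree, states: tuple[str, ...]) -> str:
    """One history as simmap-annotated Newick: each branch carries
    ``{state,duration:...}`` segments ordered from the rootward end."""
    segs = branch_segments(history, tree)

    def annotate(node: dendropy.Node) -> str:
        if node.is_leaf():
            base = node.taxon.label
        else:
            base = "(" + ",".join(annotate(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return base
        ann = ":".join(f"{states[s]},{d:.6f}" for s, d in segs[_node_key(node)])
        return f"{base}:{{{ann}}}"

    return annotate(tree.seed_node) + ";"


def summarize_node_states(histories: list[SimmapHistory], states: tuple[str, ...]) -> pd.DataFrame:
    """Per-node state frequencies across maps (rows sum to 1)."""
    if not histories:
        raise ValueError("empty history list")
    K = len(states)
    nodes = list(histories[0].node_states)
    counts = np.zeros((len(nodes), K))
    idx = {n: i for i, n in enumerate(nodes)}
    for h in histories:
        for n, s in h.node_states.items():
            counts[idx[n], s] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=list(states))
    df.insert(0, "node", nodes)
    return df


def marginal_ancestral_posteriors(
    tree: dendropy.Tree,
    tips: TipStateMatrix,
    model: MkModel,
) -> pd.DataFrame:
    """Exact marginal posterior state probabilities per node
    (up-down algorithm); the independent check for mapped frequencies."""
    _check_tip_labels(tree, tips)
    label_internal_nodes(tree)
    P = _branch_transition_matrices(tree, model.Q)
    L, _ = _partials(tree, tips, P)
    root = tree.seed_node
    up: dict = {root: model.root_prior.copy()}
    rows, nodes = [], []
    for node in tree.preorder_node_iter():
        if node is not root:
            parent = node.parent_node
            # message to this node from the rest of the tree
            sib_prod = up[parent].copy()
            for child in parent.child_nodes():
                if child is not node:
                    sib_prod = sib_prod * (P[child] @ L[child])
            msg = P[node].T @ sib_prod
            s = msg.max()
            up[node] = msg / s if s > 0 else msg
        post = up[node] * L[node]
        post = post / post.sum()
        nodes.append(_node_key(node))
        rows.append(post)
    df = pd.DataFrame(np.array(rows), columns=list(model.states))
    df.insert(0, "node", nodes)
    return df


# ---------------------------------------------------------------------------
# turnover counting and statistics
# ---------------------------------------------------------------------------

UNKNOWN = "unknown"
SCOPES = ("interspecific", "intraspecific", "homologous")


@dataclass
class TurnoverEvent:
    """One sex-chromosome turnover: the branch it occurs on, ancestral
    and derived chromosome state (or ``unknown``), ancestral and
    derived heterogamety system (XY/ZW), and its scope."""

    branch: str
    ancestral_state: str
    derived_state: str
    ancestral_system: str = "XY"
    derived_system: str = "XY"
    scope: str = "interspecific"

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        for s in (self.ancestral_system, self.derived_system):
            if s not in ("XY", "ZW"):
                raise ValueError(f"system must be XY or ZW, got {s!r}")
        if self.scope == "homologous" and self.ancestral_state != self.derived_state:
            raise ValueError("homologous turnover must keep the chromosome")

    @property
    def preserves_heterogamety(self) -> bool:
        return self.ancestral_system == self.derived_system


@dataclass
class TurnoverHistory:
    """A list of turnover events with summary accessors."""

    events: list[TurnoverEvent] = field(default_factory=list)
    unresolved_branches: list[str] = field(default_factory=list)

    def total(self) -> int:
        return len(self.events)

    def count_by_scope(self) -> dict[str, int]:
        return {s: sum(1 for e in self.events if e.scope == s) for s in SCOPES}

    def n_preserving_heterogamety(self) -> int:
        return sum(1 for e in self.events if e.preserves_heterogamety)

    def system_change_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            key = f"{e.ancestral_system}->{e.derived_system}"
            out[key] = out.get(key, 0) + 1
        return out

    def recruitments_per_chromosome(self) -> dict[str, int]:
        """Independent turnovers per derived chromosome; events with an
        unknown derived state count in totals but not here."""
        out: dict[str, int] = {}
        for e in self.events:
            if e.derived_state == UNKNOWN:
                continue
            out[e.derived_state] = out.get(e.derived_state, 0) + 1
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])


def count_turnovers(
    histories: list[SimmapHistory] | None = None,
    tree: dendropy.Tree | None = None,
    states: tuple[str, ...] = DEFAULT_STATES,
    fixture: TurnoverHistory | None = None,
    extra_events: list[TurnoverEvent] | None = None,
) -> TurnoverHistory:
    """Count turnovers from stochastic maps or a curated event table.

    From maps: each branch's endpoint states are summarised by the
    majority state across maps; a branch carries a turnover when the
    two majorities differ.  Majority ties are reported as unresolved
    branches, not events.  ``extra_events`` (e.g. intraspecific or
    homologous turnovers known from other evidence) are appended.
    """
    if fixture is not None:
        result = TurnoverHistory(list(fixture.events), list(fixture.unresolved_branches))
    else:
        if histories is None or tree is None:
            raise ValueError("need either fixture or (histories and tree)")
        K = len(states)
        node_names = list(histories[0].node_states)
        counts = {n: np.zeros(K, dtype=int) for n in node_names}
        for h in histories:
            for n, s in h.node_states.items():
                counts[n][s] += 1

        def majority(name: str) -> int | None:
            c = counts[name]
            top = c.max()
            winners = np.flatnonzero(c == top)
            return int(winners[0]) if winners.size == 1 else None

        events: list[TurnoverEvent] = []
        unresolved: list[str] = []
        label_internal_nodes(tree)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child_key, parent_key = _node_key(node), _node_key(node.parent_node)
            mp, mc = majority(parent_key), majority(child_key)
            if mp is None or mc is None:
                unresolved.append(child_key)
                continue
            if mp != mc:
                events.append(TurnoverEvent(child_key, states[mp], states[mc]))
        result = TurnoverHistory(events, unresolved)
    if extra_events:
        result.events.extend(extra_events)
    return result


def turnover_rate(tree: dendropy.Tree, n_events: int) -> tuple[float, float]:
    """Turnovers per Myr of independent evolution (total branch length)
    and its reciprocal (Myr of evolution per turnover)."""
    L = total_branch_length(tree)
    if L <= 0:
        raise ValueError("tree has zero total branch length")
    rate = n_events / L
    return rate, (np.inf if rate == 0 else 1.0 / rate)


def heterogamety_binomial(
    n_preserved: int,
    n_total: int,
    p0: float = 0.5,
    alternative: str = "greater",
) -> float:
    """Exact binomial tail probability for heterogamety preservation.

    ``greater`` gives P(X >= n_preserved | n_total, p0); ``two-sided``
    the exact two-sided test.
    """
    if not 0 <= n_preserved <= n_total:
        raise ValueError("need 0 <= n_preserved <= n_total")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if alternative == "greater":
        return float(stats.binom.sf(n_preserved - 1, n_total, p0))
    return float(stats.binomtest(n_preserved, n_total, p0, alternative=alternative).pvalue)


# ---------------------------------------------------------------------------
# recruitment null and regression
# ---------------------------------------------------------------------------


@dataclass
class RecruitmentTestConfig:
    gene_counts: dict[str, int]
    n_recruitments: int = 13
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.gene_counts.values()):
            raise ValueError("gene counts must be positive")
        if self.n_recruitments < 1:
            raise ValueError("n_recruitments must be >= 1")
        if self.n_recruitments > sum(self.gene_counts.values()):
            raise ValueError("cannot sample more genes than the genome holds")


@dataclass
class RecruitmentNullResult:
    chromosomes: list[str]
    null: np.ndarray  # (n_replicates, n_chromosomes)
    observed: dict[str, int]
    p_upper: dict[str, float]  # (r + 1) / (n + 1) corrected
    p_upper_raw: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosomes,
                "observed": [self.observed.get(c, 0) for c in self.chromosomes],
                "null_mean": self.null.mean(axis=0),
                "null_q99": np.percentile(self.null, 99, axis=0),
                "p_upper": [self.p_upper[c] for c in self.chromosomes],
            }
        )


def recruitment_null_test(
    cfg: RecruitmentTestConfig,
    observed: dict[str, int],
) -> RecruitmentNullResult:
    """Gene-resampling null for chromosome recruitment.

    Each replicate draws ``n_recruitments`` genes uniformly without
    replacement from the pooled genome and tallies their chromosomes;
    the upper-tail probability per chromosome is the fraction of
    replicates with a count >= observed, reported both raw and with
    the (r + 1)/(n + 1) correction.
    """
    chroms = list(cfg.gene_counts)
    extra = set(observed) - set(chroms)
    if extra:
        raise ValueError(f"observed recruitments on chromosomes without gene counts: {sorted(extra)}")
    if sum(observed.values()) > cfg.n_recruitments:
        raise ValueError("observed recruitments exceed n_recruitments")
    rng = np.random.default_rng(cfg.seed)
    colors = np.array([cfg.gene_counts[c] for c in chroms], dtype=np.int64)
    null = rng.multivariate_hypergeometric(colors, cfg.n_recruitments, size=cfg.n_replicates)
    p_raw, p_corr = {}, {}
    for k, c in enumerate(chroms):
        obs = observed.get(c, 0)
        r = int((null[:, k] >= obs).sum())
        p_raw[c] = r / cfg.n_replicates
        p_corr[c] = (r + 1) / (cfg.n_replicates + 1)
    return RecruitmentNullResult(chroms, null, dict(observed), p_corr, p_raw)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def recruitment_regression(recruit_counts, gene_counts) -> RegressionResult:
    """OLS of recruitment counts on gene counts, with R^2 and the
    slope t-test p-value."""
    import statsmodels.api as sm

    y = np.asarray(recruit_counts, dtype=float)
    x = np.asarray(gene_counts, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("recruit_counts and gene_counts must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need at least 3 chromosomes")
    if np.ptp(x) == 0:
        raise ValueError("gene counts have zero variance")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
    )
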