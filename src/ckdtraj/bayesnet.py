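"""Bayesian-network structure discovery over discretized checkup variables.

The learner is constraint-based:

* the G² likelihood-ratio test of (conditional) independence for discrete
  variables, referred to a chi-square distribution;
* IAMB (incremental association Markov blanket): a grow phase that
  repeatedly admits the variable with maximal conditional mutual
  information with the target given the current blanket, followed by a
  shrink phase that evicts false positives;
* a skeleton from symmetrized blankets (AND rule) with a separating-set
  search inside the blanket union to remove spouse links, v-structure
  orientation from those separating sets, Meek-style propagation, and a
  deterministic lexicographic fallback so the output is always a DAG;
* nonparametric bootstrap averaging of the learned structure, with arc
  strength = fraction of replicates containing the (directed) arc.

Continuous covariates are dichotomized at the cutoff maximizing Youden's J
on an ROC curve against the outcome, or at fixed configured cutoffs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .staging import PrognosticCategory, classify_comorbidities, outcome
from . import staging

__all__ = ["DiscreteDataset", "CITestResult", "BayesNet",
           "discretize_by_roc", "g2_ci_test", "iamb_markov_blanket",
           "learn_structure", "bootstrap_average", "build_bn_dataset",
           "CKDBayesNet", "BayesNetResults", "DEFAULT_CUTOFFS"]

#: Default dichotomization cutoffs (value >= cutoff codes as 1) for the
#: baseline continuous covariates: age in years, BMI in kg/m^2, waist
#: circumference in cm.
DEFAULT_CUTOFFS = {"age": 46.0, "bmi": 22.8, "waist": 81.4}


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    dof: int
    p_value: float


@dataclass
class DiscreteDataset:
    """Fully observed discrete data matrix with named variables.

    ``codes`` holds per-variable level indices (n x p, int); ``levels``
    the label list of each variable; ``outcome_var`` the designated
    outcome variable name (optional).
    """

    names: list[str]
    levels: dict[str, list]
    codes: np.ndarray
    outcome_var: str | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.names):
            raise ValueError("codes must be n x p with p == len(names)")
        for j, name in enumerate(self.names):
            k = len(self.levels[name])
            col = self.codes[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= k:
                raise ValueError(f"codes of {name!r} outside its level set")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def cardinality(self, name: str) -> int:
        return len(self.levels[name])

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.names.index(name)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   outcome_var: str | None = None) -> "DiscreteDataset":
        """Build from a DataFrame, factorizing each column (sorted levels)."""
        if df.isna().any().any():
            raise ValueError("dataset must have no missing cells")
        names = list(df.columns)
        levels, cols = {}, []
        for name in names:
            lv = sorted(pd.unique(df[name]).tolist())
            levels[name] = lv
            lut = {v: i for i, v in enumerate(lv)}
            cols.append(df[name].map(lut).to_numpy(dtype=np.int64))
        return cls(names, levels, np.column_stack(cols) if cols
                   else np.empty((len(df), 0), dtype=np.int64), outcome_var)

    def resample(self, rng: np.random.Generator) -> "DiscreteDataset":
        idx = rng.integers(0, self.n, size=self.n)
        return DiscreteDataset(self.names, self.levels, self.codes[idx],
                               self.outcome_var)


@dataclass
class BayesNet:
    """Directed graph over named variables, optionally with per-arc
    bootstrap strengths (fraction of replicates containing the arc)."""

    nodes: list[str]
    arcs: list[tuple[str, str]]
    strength: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a in self.arcs:
            g.add_edge(*a, strength=self.strength.get(a))
        return g

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def to_dot(self) -> str:
        lines = ["digraph bayesnet {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            s = self.strength.get((u, v))
            lbl = f' [label="{s:.2f}"]' if s is not None else ""
            lines.append(f'  "{u}" -> "{v}"{lbl};')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"from": u, "to": v,
                 "strength": self.strength.get((u, v), np.nan)}
                for u, v in sorted(self.arcs)]
        return pd.DataFrame(rows, columns=["from", "to", "strength"])


# ---------------------------------------------------------------------------
# ROC discretization


def discretize_by_roc(values, outcome_flags) -> float:
    """Cutoff maximizing Youden's J for predicting a binary outcome.

    The rule is ``value >= cutoff`` -> predicted positive; candidate
    cutoffs are the observed values.  Ties in J resolve to the smallest
    cutoff.  Raises if the outcome has a single class.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome_flags, dtype=int)
    if v.shape != y.shape or v.ndim != 1 or len(v) < 2:
        raise ValueError("values and outcome must be equal-length vectors "
                         "of length >= 2")
    pos, neg = int(y.sum()), int((1 - y).sum())
    if pos == 0 or neg == 0:
        raise ValueError("degenerate outcome: both classes required")
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    # at cutoff vs[i], positives predicted are indices j with vs[j] >= vs[i]
    cut_idx = np.flatnonzero(np.diff(vs, prepend=-np.inf) > 0)
    tp_from = np.cumsum(ys[::-1])[::-1]          # positives at >= index i
    fp_from = np.cumsum((1 - ys)[::-1])[::-1]
    j_stat = tp_from[cut_idx] / pos - fp_from[cut_idx] / neg
    best = np.flatnonzero(j_stat == j_stat.max())[0]
    return float(vs[cut_idx[best]])


def youden_j(values, outcome_flags, cutoff) -> float:
    """Sensitivity + specificity - 1 of the rule value >= cutoff."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome_flags, dtype=int)
    pred = v >= cutoff
    sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
    spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
    return float(sens + spec - 1.0)


# ---------------------------------------------------------------------------
# G^2 conditional independence test


def g2_ci_test(x: str, y: str, conditioning_set, data: DiscreteDataset,
               ) -> CITestResult:
    """G² likelihood-ratio test of X ⊥ Y | Z on discrete data.

    Within each stratum of the conditioning variables,
    ``G² += 2 Σ O·ln(O/E)`` over the X x Y contingency cells with
    ``E = row·col/total``; zero-observed cells contribute 0.  Each
    nonempty stratum contributes ``(|X|-1)(|Y|-1)`` degrees of freedom;
    empty strata are skipped and contribute no dof.  The p-value is the
    chi-square upper tail (dof floored at 1).
    """
    z = list(conditioning_set)
    if x == y or x in z or y in z:
        raise ValueError("x, y and conditioning set must be disjoint")
    xv = data.column(x)
    yv = data.column(y)
    kx, ky = data.cardinality(x), data.cardinality(y)
    if z:
        zcode = np.zeros(data.n, dtype=np.int64)
        mult = 1
        for name in z:
            zcode += data.column(name) * mult
            mult *= data.cardinality(name)
        nz = mult
    else:
        zcode = np.zeros(data.n, dtype=np.int64)
        nz = 1

    flat = (zcode * kx + xv) * ky + yv
    counts = np.bincount(flat, minlength=nz * kx * ky) \
        .reshape(nz, kx, ky).astype(float)
    totals = counts.sum(axis=(1, 2))
    nonempty = totals > 0
    rows = counts.sum(axis=2)                       # (nz, kx)
    cols = counts.sum(axis=1)                       # (nz, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows[:, :, None] * cols[:, None, :] \
            / np.where(totals > 0, totals, 1.0)[:, None, None]
        ratio = np.where(counts > 0, counts / np.where(expected > 0,
                                                       expected, 1.0), 1.0)
        g2 = 2.0 * float((counts * np.log(ratio)).sum())
    dof = max(int(nonempty.sum()) * (kx - 1) * (ky - 1), 1)
    p = float(stats.chi2.sf(g2, dof)) if g2 > 0 else 1.0
    return CITestResult(statistic=float(g2), dof=int(dof), p_value=p)


# ---------------------------------------------------------------------------
# IAMB


def iamb_markov_blanket(target: str, data: DiscreteDataset,
                        alpha: float = 0.05) -> set[str]:
    """Markov blanket of ``target`` by the incremental-association method.

    Grow phase: among variables outside the blanket, admit the one with
    the largest G² statistic (equivalently conditional mutual information)
    given the current blanket, provided its test rejects independence at
    ``alpha``; repeat until no candidate rejects.  Shrink phase: remove
    any member that is independent of the target given the rest of the
    blanket.  Ties break lexicographically, so the result is
    deterministic.
    """
    others = [v for v in data.names if v != target]
    blanket: list[str] = []
    # grow
    while True:
        best_name, best_stat, best_p = None, -np.inf, 1.0
        for cand in sorted(set(others) - set(blanket)):
            res = g2_ci_test(cand, target, blanket, data)
            if res.statistic > best_stat + 1e-12:
                best_name, best_stat, best_p = cand, res.statistic, res.p_value
        if best_name is None or best_p >= alpha:
            break
        blanket.append(best_name)
    # shrink
    changed = True
    while changed:
        changed = False
        for member in sorted(blanket):
            rest = [b for b in blanket if b != member]
            res = g2_ci_test(member, target, rest, data)
            if res.p_value >= alpha:
                blanket.remove(member)
                changed = True
                break
    return set(blanket)


def _find_sepset(x: str, y: str, candidates: set[str],
                 data: DiscreteDataset, alpha: float,
                 max_size: int = 3):
    """Smallest subset of ``candidates`` separating x from y at alpha, or
    None.  Subsets are scanned by size then lexicographically."""
    cand = sorted(candidates)
    for size in range(0, min(len(cand), max_size) + 1):
        for subset in itertools.combinations(cand, size):
            if g2_ci_test(x, y, list(subset), data).p_value >= alpha:
                return set(subset)
    return None


def learn_structure(data: DiscreteDataset, alpha: float = 0.05) -> BayesNet:
    """Learn a DAG: IAMB blankets -> skeleton -> orientation.

    Skeleton: X–Y is kept iff each is in the other's blanket (AND rule)
    and no separating set exists within the union of their blankets
    (removing spouse links).  V-structures X→Z←Y are oriented where Z is a
    common neighbour of a separated pair and Z is outside the separating
    set; Meek-style propagation avoids new v-structures and cycles;
    remaining edges are oriented from the lexicographically smaller
    endpoint, which cannot create a cycle among themselves and is
    deterministic.
    """
    if len(data.names) < 2:
        raise ValueError("need at least 2 variables")
    blankets = {v: iamb_markov_blanket(v, data, alpha) for v in data.names}

    undirected: set[frozenset] = set()
    sepsets: dict[frozenset, set[str]] = {}
    for x, y in itertools.combinations(sorted(data.names), 2):
        if y in blankets[x] and x in blankets[y]:
            cand = (blankets[x] | blankets[y]) - {x, y}
            sep = _find_sepset(x, y, cand, data, alpha)
            if sep is None:
                undirected.add(frozenset((x, y)))
            else:
                sepsets[frozenset((x, y))] = sep
        else:
            sepsets[frozenset((x, y))] = (blankets[x] - {y}) \
                if y not in blankets[x] else (blankets[y] - {x})

    g = nx.DiGraph()
    g.add_nodes_from(data.names)
    oriented: set[tuple[str, str]] = set()
    # v-structures
    for pair, sep in sorted(sepsets.items(), key=lambda kv: sorted(kv[0])):
        x, y = sorted(pair)
        for z in sorted(data.names):
            if z in (x, y) or z in sep:
                continue
            if frozenset((x, z)) in undirected and frozenset((y, z)) in undirected:
                oriented.add((x, z))
                oriented.add((y, z))

    def creates_cycle(u, v, arcs):
        h = nx.DiGraph()
        h.add_nodes_from(data.names)
        h.add_edges_from(arcs | {(u, v)})
        return not nx.is_directed_acyclic_graph(h)

    # drop conflicting v-structure orientations (both directions claimed)
    oriented = {(u, v) for (u, v) in oriented if (v, u) not in oriented}

    remaining = {e for e in undirected
                 if not ({(tuple(sorted(e))[0], tuple(sorted(e))[1]),
                          (tuple(sorted(e))[1], tuple(sorted(e))[0])}
                         & oriented)}

    # Meek rule 1: a -> b, b - c, a not adjacent c  =>  b -> c
    changed = True
    while changed:
        changed = False
        for e in sorted(remaining, key=sorted):
            b, c = sorted(e)
            for (u, v) in [(b, c), (c, b)]:
                parents = {a for (a, w) in oriented if w == u}
                for a in parents:
                    adjacent = (frozenset((a, v)) in undirected
                                or (a, v) in oriented or (v, a) in oriented)
                    if not adjacent and not creates_cycle(u, v, oriented):
                        oriented.add((u, v))
                        remaining.discard(e)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break

    # lexicographic fallback for whatever is still undirected
    for e in sorted(remaining, key=sorted):
        u, v = sorted(e)
        if creates_cycle(u, v, oriented):
            oriented.add((v, u))
        else:
            oriented.add((u, v))

    g.add_edges_from(oriented)
    assert nx.is_directed_acyclic_graph(g)
    return BayesNet(nodes=list(data.names), arcs=sorted(g.edges()))


def bootstrap_average(data: DiscreteDataset, B: int = 200,
                      threshold: float = 0.5, seed: int = 0,
                      alpha: float = 0.05) -> BayesNet:
    """Average ``B`` bootstrap-replicate structures into one network.

    Arc strength is the direction-specific fraction of replicates whose
    learned DAG contains the arc; arcs at or above ``threshold`` are
    retained, and any directed cycle among retained arcs is broken by
    dropping its weakest arc.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tally: dict[tuple[str, str], int] = {}
    for _ in range(B):
        net = learn_structure(data.resample(rng), alpha)
        for arc in net.arcs:
            tally[arc] = tally.get(arc, 0) + 1
    strength = {arc: cnt / B for arc, cnt in tally.items()}
    kept = {arc for arc, s in strength.items() if s >= threshold}

    g = nx.DiGraph()
    g.add_nodes_from(data.names)
    g.add_edges_from(kept)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (strength[(e[0], e[1])], e))
        g.remove_edge(weakest[0], weakest[1])
    arcs = sorted(g.edges())
    return BayesNet(nodes=list(data.names), arcs=arcs,
                    strength={a: strength[a] for a in arcs})


# ---------------------------------------------------------------------------
# Dataset assembly from a staged cohort


def build_bn_dataset(cohort_df: pd.DataFrame, staged: pd.DataFrame,
                     baseline_year: int, comparison_year: int,
                     final_year: int | None = None,
                     cutoffs: dict | None = None,
                     outcome_rule: str = "very_high_at_end",
                     ) -> DiscreteDataset:
    """Assemble the 9-variable discrete dataset for one comparison year.

    Variables: binary ``outcome`` (category aggravation between baseline
    and final year, or configured end state); 4-level prognostic category
    at baseline (``progress<baseline>``) and at the comparison year
    (``progress<comparison>``); binary hypertension / diabetes /
    dyslipidemia at baseline (``ht/dm/dl<baseline>``); and binary
    ``old/high_BMI/high_abd`` (baseline age, BMI, waist dichotomized at
    the configured cutoffs, default 46 y / 22.8 kg/m^2 / 81.4 cm).

    Complete cases only (subjects staged at baseline, comparison and final
    year).  Single-level variables are dropped with a warning.
    """
    cutoffs = dict(DEFAULT_CUTOFFS, **(cutoffs or {}))
    if final_year is None:
        final_year = int(staged["year"].max())
    for y in (baseline_year, comparison_year, final_year):
        if not (staged["year"] == y).any():
            raise ValueError(f"required year {y} missing from staged cohort")

    def cats(year):
        sub = staged.loc[staged["year"] == year, ["subject_id", "category"]]
        return sub.set_index("subject_id")["category"]

    c0, c1, cf = cats(baseline_year), cats(comparison_year), cats(final_year)
    ids = c0.index.intersection(c1.index).intersection(cf.index)

    base = cohort_df[cohort_df["year"] == baseline_year].set_index("subject_id")
    ids = ids.intersection(base.index).sort_values()

    out_flags = [int(outcome(PrognosticCategory(int(c0[i])),
                             PrognosticCategory(int(cf[i])), outcome_rule))
                 for i in ids]
    base = base.loc[ids]
    comorb = base.apply(classify_comorbidities, axis=1)

    df = pd.DataFrame({
        "outcome": out_flags,
        f"progress{baseline_year}": c0[ids].to_numpy(dtype=int),
        f"progress{comparison_year}": c1[ids].to_numpy(dtype=int),
        f"ht{baseline_year}": [int(c.hypertension) for c in comorb],
        f"dm{baseline_year}": [int(c.dm) for c in comorb],
        f"dl{baseline_year}": [int(c.dyslipidemia) for c in comorb],
        f"old{baseline_year}": (base["age"] >= cutoffs["age"]).astype(int).to_numpy(),
        "high_BMI": (base["bmi"] >= cutoffs["bmi"]).astype(int).to_numpy(),
        "high_abd": (base["waist"] >= cutoffs["waist"]).astype(int).to_numpy(),
    }, index=ids)

    degenerate = [c for c in df.columns if df[c].nunique() < 2]
    if degenerate:
        warnings.warn(
            f"dropping single-level variable(s): {degenerate}", UserWarning)
        df = df.drop(columns=degenerate)
    return DiscreteDataset.from_frame(df.reset_index(drop=True),
                                      outcome_var="outcome")


# ---------------------------------------------------------------------------
# Model / Results wrappers


class CKDBayesNet:
    """Structure-learning model over a discrete dataset.

    Parameters
    ----------
    data : DiscreteDataset
        Fully observed discrete dataset (e.g. from :func:`build_bn_dataset`).
    alpha : float
        Per-test significance level of the G² conditional-independence
        tests (default 0.05).
    """

    def __init__(self, data: DiscreteDataset, alpha: float = 0.05):
        self.data = data
        self.alpha = alpha

    def fit(self, B: int = 200, threshold: float = 0.5,
            seed: int = 0) -> "BayesNetResults":
        """Bootstrap-averaged structure learning; see
        :func:`bootstrap_average` for the averaging semantics."""
        net = bootstrap_average(self.data, B=B, threshold=threshold,
                                seed=seed, alpha=self.alpha)
        return BayesNetResults(self, net, B=B, threshold=threshold, seed=seed)


@dataclass
class BayesNetResults:
    model: CKDBayesNet
    network: BayesNet
    B: int
    threshold: float
    seed: int

    def summary(self) -> str:
        lines = ["Bayesian network (bootstrap-averaged IAMB structure)",
                 f"  n = {self.model.data.n}, variables = "
                 f"{len(self.model.data.names)}, alpha = {self.model.alpha}",
                 f"  B = {self.B}, strength threshold = {self.threshold}",
                 "",
                 f"{'from':>16} {'to':>16} {'strength':>9}"]
        for u, v in self.network.arcs:
            s = self.network.strength.get((u, v), float("nan"))
            lines.append(f"{u:>16} {v:>16} {s:9.2f}")
        if not self.network.arcs:
            lines.append("  (no arcs retained)")
        return "\n".join(lines)
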