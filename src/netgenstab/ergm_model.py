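"""Sufficient statistics and change statistics for the valued ERGM.

The model is an exponential-family distribution over symmetric count
networks y with a Poisson reference measure h(y) = prod_{i<j} 1/y_ij!:

    P(y) = h(y) exp(theta . g(y)) / kappa(theta)

The six statistics g implemented here capture: Conway--Maxwell--Poisson
dispersion of edge weights (``cmp``), sparsity (``nonzero``), triadic
closure on weighted ties (``transitive_ties``), a sex main effect on total
interaction strength with females as the reference level
(``nodefactor_sex_male``), sex homophily (``nodematch_sex``), and the
inverse-distance dyadic covariate between emergence locations
(``edgecov_closeness``).

Sign conventions: with the +sum log(y_ij!) CMP statistic against the
Poisson reference, edge weights follow prod (y_ij!)^(theta_cmp - 1) times
the exponential terms, so theta_cmp > 0 produces over-dispersion relative
to Poisson and theta_cmp = 1 a geometric-tailed distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import gammaln

from .netdata import ClosenessMatrix, ValuedNetwork

TERMS = (
    "cmp",
    "nonzero",
    "transitive_ties",
    "nodefactor_sex_male",
    "nodematch_sex",
    "edgecov_closeness",
)


@dataclass(frozen=True)
class ERGMSpec:
    """Ordered term list defining the model's sufficient statistics.

    ``transitive`` selects the valued transitive-ties statistic: ``minmax``
    (default) is sum_{i<j} min(y_ij, max_k min(y_ik, y_kj)); ``binary``
    applies the same formula to the presence/absence projection.
    """

    terms: tuple[str, ...] = TERMS
    transitive: str = "minmax"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown ERGM term(s): {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate ERGM terms")
        if self.transitive not in ("minmax", "binary"):
            raise ValueError("transitive must be 'minmax' or 'binary'")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def indices(self) -> np.ndarray:
        """Positions of this spec's terms within the canonical TERMS order."""
        return np.array([TERMS.index(t) for t in self.terms])


@dataclass
class ThetaVector:
    """Coefficient vector aligned to an :class:`ERGMSpec` term list."""

    terms: tuple[str, ...]
    values: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self):
        self.terms = tuple(self.terms)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.terms),):
            raise ValueError("theta length does not match term list")
        if not np.isfinite(self.values).all():
            raise ValueError("theta must be finite")
        if self.se is not None:
            self.se = np.asarray(self.se, float)
            if self.se.shape != (len(self.terms),):
                raise ValueError("se length does not match term list")

    def __getitem__(self, term: str) -> float:
        return float(self.values[self.terms.index(term)])

    def full6(self) -> np.ndarray:
        """Pad to the canonical 6-term order, zeros for absent terms."""
        out = np.zeros(len(TERMS))
        for t, v in zip(self.terms, self.values):
            out[TERMS.index(t)] = v
        return out

    def restrict(self, keep: tuple[str, ...]) -> "ThetaVector":
        """Zero out coefficients of terms not in ``keep`` (same term list)."""
        vals = np.array(
            [v if t in keep else 0.0 for t, v in zip(self.terms, self.values)]
        )
        return ThetaVector(self.terms, vals)

    def to_dict(self) -> dict:
        d = {"terms": list(self.terms), "values": self.values.tolist()}
        if self.se is not None:
            d["se"] = self.se.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThetaVector":
        return cls(tuple(d["terms"]), np.array(d["values"], float),
                   None if d.get("se") is None else np.array(d["se"], float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ThetaVector":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Numba kernels (shared with the sampler)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _two_path_max(W, a, b, binary):
    """max_k min(W[a,k], W[k,b]) over k not in {a, b}.

    Uses symmetry (W[k,b] = W[b,k]) so both reads stream along rows.
    """
    n = W.shape[0]
    tp = 0
    for k in range(n):
        if k == a or k == b:
            continue
        x = W[a, k]
        y = W[b, k]
        m = x if x < y else y
        if binary and m > 1:
            m = 1
        if m > tp:
            tp = m
    return tp


@njit(cache=True)
def _transitive_stat(W, binary):
    n = W.shape[0]
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            w = W[i, j]
            if w == 0:
                continue
            if binary and w > 1:
                w = 1
            tp = _two_path_max(W, i, j, binary)
            s += w if w < tp else tp
    return s


@njit(cache=True)
def _delta_transitive(W, a, b, w_new, binary):
    """Change in the transitive-ties statistic from setting y_ab <- w_new.

    Only the dyad itself and dyads sharing a common neighbour with (a, b)
    are affected, so the cost is O(n * |N(a) & N(b)|).
    """
    w_old = W[a, b]
    if binary:
        wo = 1 if w_old > 0 else 0
        wn = 1 if w_new > 0 else 0
    else:
        wo = w_old
        wn = w_new
    if wo == wn:
        return 0
    n = W.shape[0]
    tp = _two_path_max(W, a, b, binary)
    d = (wn if wn < tp else tp) - (wo if wo < tp else tp)
    for j in range(n):
        if j == a or j == b:
            continue
        waj = W[a, j]
        wbj = W[b, j]
        if binary:
            waj = 1 if waj > 0 else 0
            wbj = 1 if wbj > 0 else 0
        if waj == 0 or wbj == 0:
            continue
        # dyad (a, j): the k = b two-path element is min(y_ab, y_bj)
        tpo = 0
        for k in range(n):
            if k == a or k == j or k == b:
                continue
            x = W[a, k]
            y = W[j, k]
            m = x if x < y else y
            if binary and m > 1:
                m = 1
            if m > tpo:
                tpo = m
        e_old = wo if wo < wbj else wbj
        e_new = wn if wn < wbj else wbj
        tp_old = tpo if tpo > e_old else e_old
        tp_new = tpo if tpo > e_new else e_new
        d += (waj if waj < tp_new else tp_new) - (waj if waj < tp_old else tp_old)
        # dyad (b, j): the k = a two-path element is min(y_ab, y_aj)
        tpo = 0
        for k in range(n):
            if k == b or k == j or k == a:
                continue
            x = W[b, k]
            y = W[j, k]
            m = x if x < y else y
            if binary and m > 1:
                m = 1
            if m > tpo:
                tpo = m
        e_old = wo if wo < waj else waj
        e_new = wn if wn < waj else waj
        tp_old = tpo if tpo > e_old else e_old
        tp_new = tpo if tpo > e_new else e_new
        d += (wbj if wbj < tp_new else tp_new) - (wbj if wbj < tp_old else tp_old)
    return d


# ---------------------------------------------------------------------------
# Public statistic API
# ---------------------------------------------------------------------------

def _covariates(net: ValuedNetwork, spec: ERGMSpec,
                closeness: ClosenessMatrix | None):
    male = net.nodes.male.astype(np.int64)
    if "edgecov_closeness" in spec.terms:
        if closeness is None:
            raise ValueError(
                "edgecov_closeness term requires a ClosenessMatrix"
            )
        C = closeness.values
        if C.shape != net.weights.shape:
            raise ValueError("closeness matrix does not match network size")
    else:
        C = np.zeros_like(net.weights, float)
    return male, C


def sufficient_statistics(
    net: ValuedNetwork,
    spec: ERGMSpec = ERGMSpec(),
    closeness: ClosenessMatrix | None = None,
) -> np.ndarray:
    """g(y) for every term of ``spec``, over unordered dyads i < j."""
    male, C = _covariates(net, spec, closeness)
    W = net.weights
    triu = np.triu_indices(net.n, 1)
    wt = W[triu]
    full = np.zeros(len(TERMS))
    full[0] = gammaln(wt + 1.0).sum()
    full[1] = int((wt > 0).sum())
    full[2] = float(_transitive_stat(W, spec.transitive == "binary"))
    strength = W.sum(axis=1)
    full[3] = float((strength * male).sum())
    same = (male[:, None] == male[None, :])
    full[4] = 0.5 * float((W * same).sum()) - 0.0  # diagonal is zero
    full[5] = 0.5 * float((W * C).sum())
    return full[spec.indices()]


def change_statistic(
    net: ValuedNetwork,
    dyad: tuple[int, int],
    new_value: int,
    spec: ERGMSpec = ERGMSpec(),
    closeness: ClosenessMatrix | None = None,
) -> np.ndarray:
    """g(y with y_ij <- new_value) - g(y), in O(n) per dyad."""
    i, j = dyad
    if i == j:
        raise ValueError("dyad must join two distinct nodes")
    if new_value < 0:
        raise ValueError("new_value must be non-negative")
    male, C = _covariates(net, spec, closeness)
    W = net.weights
    w_old = int(W[i, j])
    dw = new_value - w_old
    full = np.zeros(len(TERMS))
    full[0] = gammaln(new_value + 1.0) - gammaln(w_old + 1.0)
    full[1] = (1 if new_value > 0 else 0) - (1 if w_old > 0 else 0)
    full[2] = float(
        _delta_transitive(W, i, j, new_value, spec.transitive == "binary")
    )
    full[3] = dw * (male[i] + male[j])
    full[4] = dw * (1 if male[i] == male[j] else 0)
    full[5] = dw * C[i, j]
    return full[spec.indices()]
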