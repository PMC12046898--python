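"""Differentially accumulated metabolites and gene-metabolite networks.

DAM screening combines a group-mean fold change (> 2 or < 0.5, strict) with
a variable-importance-in-projection score (VIP > 1) from a PLS-DA model fit
by NIPALS on autoscaled log intensities. The correlation network keeps, per
metabolite, the top-5 genes by |Pearson r| (on log2-transformed values)
that clear |r| > 0.8, with edge sign recording the correlation direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

EPS = 1e-9


@dataclass
class VIPResult:
    vip: pd.Series  # per variable; NaN for excluded zero-variance columns
    weights: np.ndarray  # (A, p) unit-norm X weights
    scores: np.ndarray  # (n, A) X scores
    ssy: np.ndarray  # (A,) explained Y sum of squares per component
    n_components: int


def _nipals_pls2(X: np.ndarray, Y: np.ndarray, n_components: int,
                 tol: float = 1e-12, max_iter: int = 500):
    """NIPALS PLS2. X and Y are centered (X autoscaled); returns unit-norm
    weights, scores and per-component explained-Y sums of squares."""
    Xa, Ya = X.copy(), Y.copy()
    n, p = Xa.shape
    W = np.zeros((n_components, p))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        u = Ya[:, np.argmax(Ya.var(axis=0))].copy()
        t = np.zeros(n)
        t_old = None
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xa @ w
            tt = t @ t
            if tt == 0:
                break
            q = Ya.T @ t / tt
            qq = q @ q
            if qq == 0:
                break
            u = Ya @ q / qq
            if t_old is not None and np.linalg.norm(t - t_old) <= \
                    tol * np.linalg.norm(t):
                break
            t_old = t
        tt = t @ t
        if tt == 0:
            W, T, ssy = W[:a], T[:, :a], ssy[:a]
            break
        pvec = Xa.T @ t / tt
        q = Ya.T @ t / tt
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, q)
        W[a], T[:, a] = w, t
        ssy[a] = tt * (q @ q)
    return W, T, ssy


def plsda_vip(X, y, n_components: int = 2,
              log_transform: bool = True) -> VIPResult:
    """VIP scores from a PLS-DA model.

    X: samples x variables (DataFrame or array); y: group labels.
    Variables are autoscaled (after optional log2(x+1)); Y is the centered
    one-hot group indicator. VIP_j = sqrt(p * sum_a SSY_a w_aj^2 /
    sum_a SSY_a) with unit-norm weights, so mean(VIP^2) = 1 over the
    modeled variables.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    M = X.to_numpy(dtype=float)
    if log_transform:
        M = np.log2(M + 1.0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance "
                      "variable(s) from the PLS-DA model")
    Mk = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    Y = np.stack([(y == lv).astype(float) for lv in levels], axis=1)
    Y = Y - Y.mean(axis=0)
    n_components = min(n_components, Mk.shape[0] - 1, Mk.shape[1])
    W, T, ssy = _nipals_pls2(Mk, Y, n_components)
    p_kept = Mk.shape[1]
    denom = ssy.sum()
    if denom == 0:
        # the model separates nothing: no variable is important
        warnings.warn("PLS-DA model explains no Y variance; VIP set to 0")
        vip_kept = np.zeros(p_kept)
    else:
        vip_kept = np.sqrt(p_kept * (W.T ** 2 @ ssy) / denom)
    vip = np.full(M.shape[1], np.nan)
    vip[keep] = vip_kept
    return VIPResult(pd.Series(vip, index=X.columns, name="VIP"),
                     W, T, ssy, len(ssy))


@dataclass
class DAMRecord:
    metabolite: str
    contrast: str
    fold_change: float
    vip: float
    is_dam: bool


def screen_dams(metabolites: pd.DataFrame, groups: pd.Series,
                contrast: tuple[str, str],
                n_components: int = 2) -> pd.DataFrame:
    """DAM screen between two groups: fold change of raw group means plus
    VIP from a two-group PLS-DA; is_dam requires (FC > 2 or FC < 0.5) and
    VIP > 1, strict."""
    g1, g2 = contrast
    for g in contrast:
        if not (groups == g).any():
            raise ValueError(f"group {g!r} absent")
    s1 = groups.index[groups == g1]
    s2 = groups.index[groups == g2]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("need >= 3 samples per group")
    m1 = metabolites[s1].mean(axis=1)
    m2 = metabolites[s2].mean(axis=1)
    fc = (m1 + EPS) / (m2 + EPS)
    sub = metabolites[list(s1) + list(s2)]
    labels = np.array([g1] * len(s1) + [g2] * len(s2))
    vip = plsda_vip(sub.T, labels, n_components).vip
    vip.index = metabolites.index
    return pd.DataFrame({
        "metabolite": metabolites.index, "contrast": f"{g1}_vs_{g2}",
        "fold_change": fc, "vip": vip,
        "is_dam": ((fc > 2.0) | (fc < 0.5)) & (vip > 1.0),
    }).set_index("metabolite")


@dataclass
class NetworkEdge:
    metabolite: str
    gene: str
    r: float

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


def _log_corr(A: np.ndarray, B: np.ndarray, method: str) -> np.ndarray:
    """Row-by-row correlation matrix between log2(A+1) and log2(B+1)."""
    X, Y = np.log2(A + 1.0), np.log2(B + 1.0)
    if method == "spearman":
        X = np.argsort(np.argsort(X, axis=1), axis=1).astype(float)
        Y = np.argsort(np.argsort(Y, axis=1), axis=1).astype(float)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    def _std(Z):
        Zc = Z - Z.mean(axis=1, keepdims=True)
        s = np.sqrt((Zc ** 2).sum(axis=1, keepdims=True))
        return np.divide(Zc, s, out=np.zeros_like(Zc), where=s > 0)

    return _std(X) @ _std(Y).T


def build_correlation_network(dams: pd.DataFrame, degs: pd.DataFrame,
                              r_threshold: float = 0.8, top_k: int = 5,
                              method: str = "pearson",
                              order: str = "rank_first") -> list[NetworkEdge]:
    """Signed gene-metabolite edges from matched intensity and expression
    matrices (rows = features, identical sample columns).

    Per metabolite, genes are ranked by |r| descending (ties by gene id),
    truncated to ``top_k``, then filtered to |r| > ``r_threshold``
    (rank_first); order='filter_first' filters before truncating, which
    keeps the same set here but is exposed because the rule wording allows
    both readings.
    """
    common = [c for c in dams.columns if c in set(degs.columns)]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples for correlations")
    R = _log_corr(dams[common].to_numpy(dtype=float),
                  degs[common].to_numpy(dtype=float), method)
    edges: list[NetworkEdge] = []
    genes = np.asarray(degs.index)
    for i, met in enumerate(dams.index):
        cand = sorted(zip(-np.abs(R[i]), genes, R[i]))
        if order == "rank_first":
            cand = cand[:top_k]
            cand = [c for c in cand if abs(c[2]) > r_threshold]
        elif order == "filter_first":
            cand = [c for c in cand if abs(c[2]) > r_threshold][:top_k]
        else:
            raise ValueError(f"unknown order {order!r}")
        edges.extend(NetworkEdge(str(met), str(g), float(r))
                     for _, g, r in cand)
    return edges


def edges_table(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame([(e.metabolite, e.gene, e.r, e.sign) for e in edges],
                        columns=["metabolite", "gene", "r", "sign"])


def nodes_table(edges: list[NetworkEdge],
                classes: pd.Series | None = None) -> pd.DataFrame:
    mets = sorted({e.metabolite for e in edges})
    gens = sorted({e.gene for e in edges})
    df = pd.DataFrame({
        "id": mets + gens,
        "type": ["metabolite"] * len(mets) + ["gene"] * len(gens),
    })
    if classes is not None:
        df["class"] = df["id"].map(classes).fillna("")
    return df


def to_graphml(edges: list[NetworkEdge], path,
               classes: pd.Series | None = None) -> None:
    G = nx.Graph()
    for _, row in nodes_table(edges, classes).iterrows():
        G.add_node(row["id"], **row.drop("id").to_dict())
    for e in edges:
        G.add_edge(e.metabolite, e.gene, r=e.r, sign=e.sign)
    nx.write_graphml(G, str(path))


def to_sif(edges: list[NetworkEdge], path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.metabolite}\t{e.sign}\t{e.gene}\n")
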