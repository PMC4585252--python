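"""Oxygen-zone classification, Fe:Cu regressions, Spearman screens,
rarefaction, and partial canonical correspondence analysis.

Water-column samples are classified into five oxygen zones defined
jointly by O2 concentration and depth:

==================  ==============  ===============
zone                depth (m)       O2 (µM)
==================  ==============  ===============
upper_oxic          15–30           > 200
upper_oxycline      50–85           10–200
upper_omz           70–125          < 10
core_omz            200–300         < 5
lower_oxycline      500–1000        5–50
==================  ==============  ===============

The O2 criterion is primary and depth breaks the ambiguity between zones
sharing an O2 band.  O2 bands are lower-inclusive/upper-exclusive,
depth windows inclusive on both ends; a (depth, O2) pair falling in no
box is "unclassified".

The Fe:Cu molar ratio (dissolved Fe over dissolved Cu) is regressed on
O2 by ordinary least squares; the fitted value in the zero-oxygen limit
(the intercept, for a negative slope) is the predicted maximum Fe:Cu
ratio of an anoxic water mass.

Community statistics: Spearman rank correlations (mid-rank Pearson rho;
exact permutation p below n=10, t approximation otherwise, optional
Benjamini–Hochberg q-values), rarefaction by repeated subsampling
without replacement, and CCA — a constrained ordination of the
chi-square-standardized community matrix on environmental variables,
optionally partialled on covariates.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ZONES = ("upper_oxic", "upper_oxycline", "upper_omz", "core_omz",
         "lower_oxycline", "unclassified")

GEOCHEM_COLUMNS = ("sample_id", "depth", "temperature", "o2", "no3", "no2",
                   "po4", "dfe", "dcu")


@dataclass
class GeoSample:
    sample_id: str
    depth: float
    temperature: float | None = None
    o2: float | None = None
    no3: float | None = None
    no2: float | None = None
    po4: float | None = None
    dfe: float | None = None   # nM
    dcu: float | None = None   # nM

    @property
    def fe_cu_ratio(self) -> float | None:
        if self.dfe is None or self.dcu is None or self.dcu == 0:
            return None
        return self.dfe / self.dcu

    @property
    def zone(self) -> str:
        if self.depth is None or self.o2 is None:
            return "unclassified"
        return classify_zone(self.depth, self.o2)


@dataclass
class LinearFit:
    slope: float       # ratio change per µM O2
    intercept: float   # ratio at 0 µM O2
    r_squared: float
    n: int


# depth window (inclusive) and O2 band [low, high) per zone; None = unbounded.
_ZONE_BOXES = (
    ("upper_oxic", 15.0, 30.0, 200.0, None, True),   # O2 strictly > 200
    ("upper_oxycline", 50.0, 85.0, 10.0, 200.0, False),
    ("upper_omz", 70.0, 125.0, 0.0, 10.0, False),
    ("core_omz", 200.0, 300.0, 0.0, 5.0, False),
    ("lower_oxycline", 500.0, 1000.0, 5.0, 50.0, False),
)


def classify_zone(depth: float, o2: float) -> str:
    """Oxygen-zone label for one (depth m, O2 µM) pair."""
    if depth is None or o2 is None or not np.isfinite(depth) or not np.isfinite(o2):
        _warnings.warn("missing depth or O2; sample unclassified")
        return "unclassified"
    for name, dlo, dhi, olo, ohi, strict_lo in _ZONE_BOXES:
        if not (dlo <= depth <= dhi):
            continue
        if strict_lo:
            if o2 > olo:
                return name
        elif olo <= o2 and (ohi is None or o2 < ohi):
            return name
    return "unclassified"


def load_geochem(csv_text_or_path) -> pd.DataFrame:
    """Geochemistry CSV -> DataFrame with derived fe_cu_ratio and zone."""
    import io
    src = csv_text_or_path
    if isinstance(src, str) and "\n" in src:
        src = io.StringIO(src)
    df = pd.read_csv(src)
    missing = [c for c in ("sample_id", "depth", "o2") if c not in df.columns]
    if missing:
        raise ValueError(f"geochemistry table lacks columns {missing}")
    return annotate_geochem(df)


def annotate_geochem(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "dfe" in df.columns and "dcu" in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["fe_cu_ratio"] = df["dfe"] / df["dcu"]
    df["zone"] = [
        classify_zone(d, o) if pd.notna(d) and pd.notna(o) else "unclassified"
        for d, o in zip(df["depth"], df["o2"])
    ]
    return df


def fit_fe_cu_vs_o2(samples) -> LinearFit:
    """OLS of Fe:Cu molar ratio on O2 (µM).

    ``samples`` is a DataFrame with ``o2`` and ``fe_cu_ratio`` (or ``dfe``
    and ``dcu``) columns, or a list of :class:`GeoSample`.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples
        if "fe_cu_ratio" not in df.columns:
            df = annotate_geochem(df)
        x = df["o2"].to_numpy(float)
        y = df["fe_cu_ratio"].to_numpy(float)
    else:
        pairs = [(s.o2, s.fe_cu_ratio) for s in samples
                 if s.o2 is not None and s.fe_cu_ratio is not None]
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need >= 2 complete (O2, Fe:Cu) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all O2 values identical")
    res = sps.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return LinearFit(float(res.slope), float(res.intercept), r2, len(x))


def predict_zero_oxygen(fit: LinearFit) -> float:
    """Fitted Fe:Cu ratio at O2 = 0 (the intercept).

    For a negative slope this is the predicted maximum ratio; for a
    nonnegative slope the value is still returned but flagged via a
    warning as not a maximum.
    """
    if fit.slope >= 0:
        _warnings.warn("nonnegative slope: zero-O2 value is not a maximum")
    return fit.intercept


# ---------------------------------------------------------------------------
# Spearman screen

@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    q_value: float | None = None


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson correlation of mid-ranks (ties averaged)."""
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def _perm_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p over all n! orderings of y."""
    ry = sps.rankdata(y, method="average")
    rx = sps.rankdata(x, method="average")
    rx = rx - rx.mean()
    sx = np.sqrt((rx ** 2).sum())
    perms = np.array(list(itertools.permutations(ry)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    sy = np.sqrt((pc ** 2).sum(axis=1))
    rhos = (pc @ rx) / (sx * sy)
    return float(np.mean(np.abs(rhos) >= np.abs(rho_obs) - 1e-12))


def spearman_test(x, y) -> tuple[float, float, int]:
    """(rho, two-sided p, n); exact permutation p for n < 10, t approx else."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho = spearman_rho(x, y)
    if n < 10:
        p = _perm_pvalue(x, y, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p), n


def spearman_screen(inventory: pd.DataFrame, geochem: pd.DataFrame,
                    adjust: bool = True) -> pd.DataFrame:
    """All label x variable Spearman correlations on shared samples.

    ``inventory``: samples x labels (per-100k values); ``geochem``:
    samples x environmental variables (numeric columns only are used).
    Pairwise-complete deletion per pair; constant vectors are skipped
    with a note.  Raw p is primary; BH q-values are reported alongside
    when ``adjust``.
    """
    env = geochem.select_dtypes("number")
    shared = inventory.index.intersection(env.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    inv = inventory.loc[shared]
    env = env.loc[shared]
    rows, skipped = [], []
    for label in inv.columns:
        for var in env.columns:
            x = env[var].to_numpy(float)
            y = inv[label].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                skipped.append((label, var, "fewer than 3 complete pairs"))
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                skipped.append((label, var, "constant vector"))
                continue
            rho, p, n = spearman_test(x[ok], y[ok])
            rows.append({"x": var, "y": label, "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows, columns=["x", "y", "rho", "p", "n"])
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Rarefaction

def rarefy_matrix(counts: pd.DataFrame, depth: int, reps: int = 999,
                  seed: int = 0) -> pd.DataFrame:
    """Mean of ``reps`` subsamples without replacement to ``depth`` reads.

    ``counts`` is a samples x labels integer matrix.  A sample whose
    total is below ``depth`` raises an error naming it.
    """
    rng = np.random.default_rng(seed)
    values = counts.to_numpy()
    if np.any(values < 0) or not np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.int64)
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative integers")
    out = np.zeros(values.shape, float)
    for i, sample in enumerate(counts.index):
        row = values[i]
        total = int(row.sum())
        if depth > total:
            raise ValueError(
                f"rarefaction depth {depth} exceeds total {total} of sample "
                f"{sample!r}")
        acc = np.zeros(len(row), float)
        for _ in range(reps):
            acc += rng.multivariate_hypergeometric(row, depth)
        out[i] = acc / reps
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# (partial) canonical correspondence analysis

@dataclass
class CcaResult:
    eigenvalues_constrained: np.ndarray
    eigenvalues_unconstrained: np.ndarray
    site_scores: pd.DataFrame      # linear-combination scores, rows = samples
    species_scores: pd.DataFrame   # rows = labels, scaling 2
    biplot_scores: pd.DataFrame    # rows = constraint variables
    total_inertia: float
    constrained_inertia: float
    conditioned_inertia: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def unconstrained_inertia(self) -> float:
        return float(np.sum(self.eigenvalues_unconstrained))


def _weighted_center(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return X - (w @ X)


def _project_out(Q: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Residual of Q after projection on the column span of basis."""
    if basis.size == 0:
        return Q
    U, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-10 * (s[0] if len(s) else 1.0)
    U = U[:, keep]
    return Q - U @ (U.T @ Q)


def _projection(Q: np.ndarray, basis: np.ndarray) -> np.ndarray:
    U, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-10 * (s[0] if len(s) else 1.0)
    U = U[:, keep]
    return U @ (U.T @ Q)


def partial_cca(community: pd.DataFrame, constraints: pd.DataFrame,
                conditions: pd.DataFrame | None = None,
                eps: float = 1e-12) -> CcaResult:
    """Constrained correspondence analysis, optionally partialled.

    The community matrix (samples x labels, nonnegative) is converted to
    relative totals P with row/column weights r, c; the standardized
    residual matrix Qbar_ij = (P_ij - r_i c_j) / sqrt(r_i c_j) carries
    total inertia = chi-square statistic / grand total.  Constraints are
    weighted-centered and scaled by sqrt(r); if conditions are given both
    Qbar and the constraints are first residualized on them.  The SVD of
    the projection of Qbar onto the constraint span yields the
    constrained axes (eigenvalues = squared singular values); the
    residual yields the unconstrained axes.  Species scores use the
    "scaling 2" convention (scaled by the singular value).
    """
    Y = community.to_numpy(float)
    if np.any(Y < 0) or not np.isfinite(Y).all():
        raise ValueError("community matrix must be finite and nonnegative")
    if Y.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if (Y.sum(axis=1) <= 0).any() or (Y.sum(axis=0) <= 0).any():
        raise ValueError("community matrix has empty rows or columns")
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    total_inertia = float((Qbar ** 2).sum())

    sqrt_r = np.sqrt(r)

    def env_matrix(df: pd.DataFrame) -> np.ndarray:
        X = df.loc[community.index].to_numpy(float)
        if not np.isfinite(X).all():
            raise ValueError("environmental matrix has missing values")
        return sqrt_r[:, None] * _weighted_center(X, r)

    conditioned_inertia = 0.0
    if conditions is not None:
        Zw = env_matrix(conditions)
        Qfit_z = _projection(Qbar, Zw)
        conditioned_inertia = float((Qfit_z ** 2).sum())
        Qbar = Qbar - Qfit_z
    else:
        Zw = np.zeros((Y.shape[0], 0))

    Xw = env_matrix(constraints)
    if conditions is not None:
        pre_norm = np.linalg.norm(Xw, axis=0)
        Xw = _project_out(Xw, Zw)
        # a column absorbed by the conditions is numerical noise, not signal
        dead = np.linalg.norm(Xw, axis=0) <= 1e-8 * np.maximum(pre_norm, 1e-300)
        Xw[:, dead] = 0.0

    # collinearity check on the (possibly residualized) constraints
    rank = np.linalg.matrix_rank(Xw, tol=1e-9)
    nz_cols = [j for j in range(Xw.shape[1]) if np.linalg.norm(Xw[:, j]) > 1e-12]
    if rank < len(nz_cols):
        _, Rq, piv = _qr_pivot(Xw)
        diag = np.abs(np.diag(Rq))
        bad = [constraints.columns[piv[i]] for i in range(len(diag))
               if diag[i] <= 1e-9 * diag[0]]
        raise ValueError(f"rank-deficient constraints; collinear columns: {bad}")

    Qhat = _projection(Qbar, Xw)
    U, s, Vt = np.linalg.svd(Qhat, full_matrices=False)
    keep = s ** 2 > eps
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    eig_c = s ** 2

    Qres = Qbar - Qhat
    Ur, sr, Vtr = np.linalg.svd(Qres, full_matrices=False)
    keep_r = sr ** 2 > eps
    eig_u = sr[keep_r] ** 2

    axes = [f"CCA{i+1}" for i in range(len(s))]
    with np.errstate(divide="ignore", invalid="ignore"):
        site = (U / sqrt_r[:, None])
        species = (Vt.T / np.sqrt(c)[:, None]) * s  # scaling 2
    site_scores = pd.DataFrame(site, index=community.index, columns=axes)
    species_scores = pd.DataFrame(species, index=community.columns, columns=axes)

    # biplot scores: weighted correlation of constraints with the axes
    Xn = Xw / np.maximum(np.linalg.norm(Xw, axis=0, keepdims=True), 1e-300)
    biplot = pd.DataFrame(Xn.T @ U, index=constraints.columns, columns=axes)

    return CcaResult(
        eigenvalues_constrained=eig_c,
        eigenvalues_unconstrained=eig_u,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot,
        total_inertia=total_inertia,
        constrained_inertia=float(eig_c.sum()),
        conditioned_inertia=conditioned_inertia,
        meta={"scaling": 2, "n_samples": Y.shape[0], "n_labels": Y.shape[1]},
    )


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr
    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv
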