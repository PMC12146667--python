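"""Site-use composition and permutational multivariate ANOVA (PERMANOVA).

Each analysis unit (an individual, or an individual-month) is described
by the proportion of its hourly detection presences at each receiver
site.  Between-unit dissimilarity is Bray-Curtis, and factor effects
(species, month, release site, sex, size class, interactions) are tested
with a sequential (Type-I) PERMANOVA: sums of squares are read off a
Gower-centred inner-product matrix through nested projections, and the
pseudo-F of each term is referred to its permutation distribution under
free relabelling of the units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .io import DEFAULT_TZ_HOURS


def build_use_matrix(
    detections: pd.DataFrame,
    site_exclusions: list[str] | None = None,
    unit: str = "individual_month",
    tz_hours: float = DEFAULT_TZ_HOURS,
) -> pd.DataFrame:
    """Per-unit proportions of hourly detection presence across sites.

    Detections are collapsed to presence per (unit, site, hour): two
    detections at one site within the same hour count once.  Rows are
    normalised to sum to 1; units with no detections at included sites are
    dropped.  ``unit`` is ``"individual"`` or ``"individual_month"`` (local
    calendar months).
    """
    df = detections
    if site_exclusions:
        df = df.loc[~df["receiver_id"].isin(site_exclusions)]
    if df.empty:
        raise ValueError("no detections remain after site exclusions")
    local = df["timestamp"] + pd.Timedelta(hours=tz_hours)
    hour = local.dt.floor("h")
    keys = {"tag_id": df["tag_id"], "site": df["receiver_id"], "hour": hour}
    if unit == "individual_month":
        keys["year"] = local.dt.year
        keys["month"] = local.dt.month
        unit_cols = ["tag_id", "year", "month"]
    elif unit == "individual":
        unit_cols = ["tag_id"]
    else:
        raise ValueError(f"unknown unit {unit!r}")
    pres = pd.DataFrame(keys).drop_duplicates()
    counts = pres.groupby(unit_cols + ["site"]).size().rename("hours").reset_index()
    wide = counts.pivot_table(
        index=unit_cols, columns="site", values="hours", fill_value=0.0
    )
    wide = wide.div(wide.sum(axis=1), axis=0)
    wide.columns.name = None
    return wide.reset_index()


def attach_metadata(
    use_matrix: pd.DataFrame,
    tags: pd.DataFrame,
    size_classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join species/release-site/sex (and size class) onto use-matrix rows."""
    meta_cols = ["tag_id", "species", "sex", "release_site"]
    out = use_matrix.merge(tags[meta_cols], on="tag_id", how="left")
    if size_classes is not None and len(size_classes):
        out = out.merge(
            size_classes[["tag_id", "size_class"]], on="tag_id", how="left"
        )
    return out


def bray_curtis(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis distance matrix d(u,v) = sum|u-v| / sum(u+v)."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative rows")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis is undefined for all-zero rows")
    return squareform(pdist(X, metric="braycurtis"))


def _dummy_columns(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValueError(
            f"factor with a single level cannot be tested (levels={list(levels)})"
        )
    return (values.to_numpy()[:, None] == levels[1:]).astype(float)


def _term_columns(term: str, metadata: pd.DataFrame) -> np.ndarray:
    """Model-matrix columns for a main effect ``"a"`` or interaction ``"a:b"``."""
    parts = term.split(":")
    cols = _dummy_columns(metadata[parts[0]].astype(str))
    for p in parts[1:]:
        other = _dummy_columns(metadata[p].astype(str))
        cols = np.einsum("ij,ik->ijk", cols, other).reshape(len(metadata), -1)
    return cols


class Permanova(BaseEstimator):
    """Sequential Bray-Curtis PERMANOVA over a list of factor terms.

    Parameters
    ----------
    terms : list of str
        Factor names in ``metadata`` (interactions as ``"a:b"``), added
        sequentially in this order (Type-I sums of squares).
    n_permutations : int
        Permutations for the p-values (default 999; the attainable floor is
        1 / (n_permutations + 1)).
    strata : str or None
        Optional metadata column; permutations shuffle rows only within its
        levels.  The default free permutation treats repeated rows per
        animal as exchangeable, a documented simplification.

    Attributes
    ----------
    results_ : DataFrame with df, SS, pseudo-F, R2 and permutation p per
        term plus Residual and Total rows.
    """

    def __init__(
        self,
        terms: list[str] | None = None,
        n_permutations: int = 999,
        strata: str | None = None,
        seed: int | None = None,
    ):
        self.terms = terms
        self.n_permutations = n_permutations
        self.strata = strata
        self.seed = seed

    def fit(self, D: np.ndarray, metadata: pd.DataFrame):
        """Partition the distance matrix ``D`` over the metadata terms."""
        D = np.asarray(D, dtype=float)
        n = D.shape[0]
        if D.shape != (n, n):
            raise ValueError("D must be square")
        if len(metadata) != n:
            raise ValueError("metadata rows must align with the distance matrix")
        terms = self.terms or []
        if not terms:
            raise ValueError("at least one term is required")
        metadata = metadata.reset_index(drop=True)

        # Gower-centred inner-product matrix
        A = -0.5 * D**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        ss_total = float(np.trace(G))

        # progressive orthonormal basis (intercept first), Q-blocks per term
        basis = [np.ones((n, 1)) / np.sqrt(n)]
        qblocks, dfs = [], []
        for term in terms:
            cols = _term_columns(term, metadata)
            Q = np.hstack(basis)
            resid = cols - Q @ (Q.T @ cols)
            u, s, _ = np.linalg.svd(resid, full_matrices=False)
            keep = s > 1e-8 * max(s[0], 1.0)
            newq = u[:, keep]
            if newq.shape[1] == 0:
                raise ValueError(f"term {term!r} adds no degrees of freedom")
            qblocks.append(newq)
            dfs.append(newq.shape[1])
            basis.append(newq)
        Qall = np.hstack(basis[1:])
        p_model = Qall.shape[1]
        df_res = n - 1 - p_model
        if df_res <= 0:
            raise ValueError("more model degrees of freedom than units")

        def term_ss(Gmat):
            return np.array([np.einsum("ij,ji->", q.T @ Gmat, q) for q in qblocks])

        ss_terms = term_ss(G)
        ss_res = ss_total - ss_terms.sum()
        ms_res = ss_res / df_res
        F_obs = (ss_terms / np.array(dfs)) / ms_res

        rng = np.random.default_rng(self.seed)
        counts = np.ones(len(terms))
        if self.strata is not None:
            strata_idx = list(metadata.groupby(self.strata).indices.values())
        for _ in range(self.n_permutations):
            if self.strata is None:
                perm = rng.permutation(n)
            else:
                perm = np.arange(n)
                for idx in strata_idx:
                    perm[idx] = rng.permutation(perm[idx])
            Gp = G[np.ix_(perm, perm)]
            ssp = term_ss(Gp)
            ssrp = ss_total - ssp.sum()
            Fp = (ssp / np.array(dfs)) / (ssrp / df_res)
            counts += Fp >= F_obs - 1e-12
        pvals = counts / (self.n_permutations + 1.0)

        rows = [
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_terms[i],
                "pseudo_F": F_obs[i],
                "R2": ss_terms[i] / ss_total,
                "p_perm": pvals[i],
            }
            for i, t in enumerate(terms)
        ]
        rows.append(
            {
                "term": "Residual",
                "df": df_res,
                "SS": ss_res,
                "pseudo_F": np.nan,
                "R2": ss_res / ss_total,
                "p_perm": np.nan,
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": n - 1,
                "SS": ss_total,
                "pseudo_F": np.nan,
                "R2": 1.0,
                "p_perm": np.nan,
            }
        )
        self.results_ = pd.DataFrame(rows)
        self.n_units_ = n
        return self


def permanova(
    D: np.ndarray,
    metadata: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`Permanova`; returns the table."""
    est = Permanova(
        terms=terms, n_permutations=n_permutations, seed=seed, strata=strata
    ).fit(D, metadata)
    return est.results_
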