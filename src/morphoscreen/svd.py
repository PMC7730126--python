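"""Unsupervised profiling of the colony feature matrix.

Workflow: z-score each measurement across colonies, take the thin SVD,
keep the leading components (enough to pass a cumulative-variance
threshold, capped), correlate per-colony component scores with the
phenotype frequency of each colony's well of origin, and decompose each
component's loadings by measurement family.  A hierarchical clustering of
the four phenotype frequency vectors across wells summarizes phenotype
co-occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from .effects import PHENOTYPES
from .features import FEATURE_FAMILIES

log = logging.getLogger(__name__)

__all__ = [
    "SVDResult",
    "scale_features",
    "svd_decompose",
    "select_components",
    "pc_phenotype_correlation",
    "measurement_contributions",
    "phenotype_cooccurrence_clustering",
]


def scale_features(
    feature_table: pd.DataFrame, feature_columns: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Per-measurement z-scoring (mean 0, sd 1).

    Constant measurements carry no signal and are dropped with a warning;
    the returned list names them.  Raises if nothing remains.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in feature_table.columns if c not in ("well_id", "colony_id")
        ]
    if len(feature_table) < 2:
        raise ValueError("need at least 2 colonies to scale features")
    X = feature_table.loc[:, feature_columns]
    sd = X.std(axis=0, ddof=0)
    dropped = [c for c in feature_columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if dropped:
        log.warning("dropping %d constant measurements: %s", len(dropped),
                    dropped[:5])
    kept = [c for c in feature_columns if c not in dropped]
    if not kept:
        raise ValueError("all measurements are constant")
    Z = (X[kept] - X[kept].mean(axis=0)) / sd[kept]
    return Z, dropped


@dataclass
class SVDResult:
    """Thin SVD of the scaled colony x measurement matrix.

    ``colony_scores`` holds the left singular vectors (unit norm, one column
    per component), ``loadings`` the right singular vectors; sign convention:
    the largest-|loading| entry of each component is positive.
    """

    colony_scores: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    measurement_names: list[str] = field(default_factory=list)


def svd_decompose(scaled: pd.DataFrame | np.ndarray) -> SVDResult:
    names = list(scaled.columns) if isinstance(scaled, pd.DataFrame) else []
    X = np.asarray(scaled, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("scaled matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    # sign convention: largest-|loading| entry per component made positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    var = s**2
    return SVDResult(U, V, s, var / var.sum(), names)


def select_components(
    result: SVDResult, threshold: float = 0.73, max_k: int = 10
) -> list[int]:
    """Leading components up to the cumulative-variance threshold, capped.

    Returns 0-based component indices; always at least one.
    """
    cum = np.cumsum(result.variance_explained)
    k = int(np.searchsorted(cum, threshold) + 1)
    k = max(1, min(k, max_k, len(cum)))
    return list(range(k))


def pc_phenotype_correlation(
    result: SVDResult,
    colony_wells: pd.Series,
    profiles: pd.DataFrame,
    components: list[int] | None = None,
    well_level: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of component scores with phenotype frequencies.

    By default the correlation is computed at colony level: each colony's
    score against the frequency of the phenotype in its well of origin
    (frequencies broadcast to colonies).  With ``well_level=True`` scores
    are first averaged per well.  Zero-variance frequency vectors yield
    ``undefined = True`` rather than a coefficient of 0.
    """
    if components is None:
        components = select_components(result)
    prof = profiles.set_index("well_id")
    wells = np.asarray(colony_wells)
    missing = set(wells) - set(prof.index)
    if missing:
        raise KeyError(f"profiles missing wells: {sorted(missing)[:5]}")
    rows = []
    for k in components:
        scores = result.colony_scores[:, k]
        if well_level:
            df = pd.DataFrame({"well_id": wells, "score": scores})
            agg = df.groupby("well_id")["score"].mean()
            use_wells = agg.index.to_numpy()
            xs = agg.to_numpy()
        else:
            use_wells, xs = wells, scores
        for ph in PHENOTYPES:
            ys = prof.loc[use_wells, f"f_{ph}"].to_numpy(float)
            ok = np.isfinite(ys)
            undefined = np.nanstd(ys[ok]) == 0 or np.std(xs[ok]) == 0
            if undefined:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(xs[ok], ys[ok])
            rows.append(
                {"component": k, "phenotype": ph, "pcc": r, "p_value": p,
                 "n": int(ok.sum()), "undefined": bool(undefined)}
            )
    return pd.DataFrame(rows)


def measurement_contributions(
    result: SVDResult,
    component: int,
    families: dict[str, str] = FEATURE_FAMILIES,
    top_n: int = 4,
) -> dict:
    """Family-wise loading distribution and top signed contributors.

    The absolute loadings of the component are grouped by measurement family
    (summaries of each family's distribution plus its share of total absolute
    contribution), and the ``top_n`` most positive and most negative signed
    loadings are named.
    """
    if not result.measurement_names:
        raise ValueError("SVD result carries no measurement names")
    v = result.loadings[:, component]
    names = result.measurement_names
    unknown = [n for n in names if n not in families]
    if unknown:
        raise KeyError(f"measurements missing a family tag: {unknown[:5]}")
    fam = pd.DataFrame(
        {"measurement": names, "family": [families[n] for n in names],
         "loading": v, "abs_loading": np.abs(v)}
    )
    total = fam["abs_loading"].sum()
    by_family = {
        f: {
            "share": float(g["abs_loading"].sum() / total),
            "mean_abs": float(g["abs_loading"].mean()),
            "median_abs": float(g["abs_loading"].median()),
            "max_abs": float(g["abs_loading"].max()),
            "n": int(len(g)),
        }
        for f, g in fam.groupby("family")
    }
    srt = fam.sort_values("loading")
    top_pos = srt.tail(top_n).iloc[::-1][["measurement", "loading"]]
    top_neg = srt.head(top_n)[["measurement", "loading"]]
    return {
        "component": component,
        "families": by_family,
        "top_positive": list(top_pos.itertuples(index=False, name=None)),
        "top_negative": list(top_neg.itertuples(index=False, name=None)),
    }


def phenotype_cooccurrence_clustering(profiles: pd.DataFrame) -> dict:
    """Average-linkage clustering of the four phenotypes over wells.

    Each phenotype is represented by its frequency vector across wells
    (wells with undefined profiles excluded); distance = 1 - Pearson r.
    Returns the merge tree (scipy linkage matrix), leaf order, cophenetic
    distances and the first merged pair.
    """
    cols = [f"f_{ph}" for ph in PHENOTYPES]
    prof = profiles.dropna(subset=cols)
    if len(prof) < 3:
        raise ValueError("need at least 3 wells with defined profiles")
    M = prof[cols].to_numpy(float).T  # 4 x wells
    if np.unique(M, axis=0).shape[0] < 2:
        raise ValueError("fewer than 2 distinct phenotype profiles")
    dist = pdist(M, metric="correlation")
    Z = linkage(dist, method="average")
    coph = cophenet(Z)
    first = sorted(int(i) for i in Z[0, :2])
    return {
        "linkage": Z,
        "labels": list(PHENOTYPES),
        "cophenetic": coph,
        "first_merge": (PHENOTYPES[first[0]], PHENOTYPES[first[1]]),
        "n_wells": int(len(prof)),
    }
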