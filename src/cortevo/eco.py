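"""Ecology and behaviour association statistics for cortical shape modes.

Links the outputs of phylogenetic shape modelling (pPCA mode scores,
expansion maps on a common topology) to binary ecological indicators
(diurnality, social group size, habitat), with inference that respects the
spatial non-independence of surface measurements: parcel-level statistics
are referenced to spatial-autocorrelation-matched surrogate maps, multiple
comparisons use Benjamini–Hochberg (independent tests) or
Benjamini–Yekutieli (dependent tests), and habitat effects across
functional regions use repeated-measures correlation with a continuous
habitat-complexity scale (arboreal > terrestrial > fossorial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mesh import SurfaceMesh, VertexField

__all__ = [
    "HabitatScale", "benjamini_hochberg", "benjamini_yekutieli",
    "screen_modes", "synthesize_expansion", "parcel_tests", "rmcorr",
    "habitat_scale_estimate", "decode_map", "cluster_trajectories",
    "inferential_suite",
]


@dataclass
class HabitatScale:
    """Habitat complexity on a continuous axis: arboreal=1 > terrestrial=0 > fossorial."""

    arboreal: float = 1.0
    terrestrial: float = 0.0
    fossorial: float = -0.3

    def __post_init__(self) -> None:
        if not (self.arboreal > self.terrestrial > self.fossorial):
            raise ValueError("habitat scale must order arboreal > terrestrial > fossorial")

    def as_dict(self) -> dict[str, float]:
        return {"arboreal": self.arboreal, "terrestrial": self.terrestrial,
                "fossorial": self.fossorial}


# ---------------------------------------------------------------------------
# FDR procedures (step-up rules, first principles)
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: returns (reject mask, q-values).

    q_i is the smallest alpha at which p_(i) would be rejected:
    ``q_(i) = min_{j >= i} p_(j) m / j``.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qvals = np.empty(m)
    qvals[order] = q
    reject = qvals <= alpha
    return reject, qvals


def benjamini_yekutieli(pvals: np.ndarray, alpha: float = 0.05
                        ) -> tuple[np.ndarray, np.ndarray]:
    """BY step-up for arbitrarily dependent tests: BH with p inflated by
    the harmonic factor ``c(m) = sum_{i=1..m} 1/i``."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    cm = np.sum(1.0 / np.arange(1, m + 1))
    _, q0 = benjamini_hochberg(p, alpha)
    q = np.minimum(q0 * cm, 1.0)
    return q <= alpha, q


# ---------------------------------------------------------------------------
# Mode screening
# ---------------------------------------------------------------------------

def screen_modes(scores: np.ndarray, ecology: pd.DataFrame, alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Rank-sum screen of pPCA mode scores against binary ecological variables.

    Two-sided Mann–Whitney U per (mode, variable); BH q-values across the
    whole family. Variables constant across species are skipped with a
    warning; groups need >= 3 species each.
    """
    scores = np.asarray(scores, dtype=float)
    rows = []
    for var in ecology.columns:
        g = ecology[var].to_numpy()
        if len(np.unique(g)) < 2:
            warnings.warn(f"variable '{var}' constant across species; skipped")
            continue
        if min((g == 0).sum(), (g == 1).sum()) < 3:
            warnings.warn(f"variable '{var}' has a group with < 3 species; skipped")
            continue
        for mode in range(scores.shape[1]):
            a = scores[g == 1, mode]
            b = scores[g == 0, mode]
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"mode": mode, "variable": var, "U": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], significant=[])
    reject, q = benjamini_hochberg(df["p"].to_numpy(), alpha)
    df["q"] = q
    df["significant"] = reject
    return df


# ---------------------------------------------------------------------------
# Expansion synthesis from pPCA modes
# ---------------------------------------------------------------------------

def synthesize_expansion(modes: np.ndarray, mean_shape: np.ndarray,
                         scores: np.ndarray, group: np.ndarray,
                         significant_modes: list[int],
                         reference_faces: np.ndarray) -> VertexField:
    """Expansion map between group centroids in the significant-mode span.

    Two synthetic shapes are reconstructed at the variable-positive and
    variable-negative centroids (mean shape plus the centroid scores along
    the significant modes); the per-vertex log ratio of their lumped vertex
    areas is the expansion map. Shape vectors are flattened (x, y, z)
    vertex coordinates on the common topology.
    """
    if len(significant_modes) == 0:
        raise ValueError("no significant modes to synthesize from")
    group = np.asarray(group).astype(bool)
    sig = np.asarray(significant_modes, dtype=int)
    c_pos = scores[group][:, sig].mean(axis=0)
    c_neg = scores[~group][:, sig].mean(axis=0)
    shape_pos = mean_shape + modes[:, sig] @ c_pos
    shape_neg = mean_shape + modes[:, sig] @ c_neg
    m_pos = SurfaceMesh(shape_pos.reshape(-1, 3), reference_faces)
    m_neg = SurfaceMesh(shape_neg.reshape(-1, 3), reference_faces)
    a_pos = m_pos.vertex_areas()
    a_neg = m_neg.vertex_areas()
    return VertexField(np.log(np.maximum(a_pos, 1e-300) / np.maximum(a_neg, 1e-300)),
                       "expansion")


# ---------------------------------------------------------------------------
# Parcel-level inference with surrogate nulls
# ---------------------------------------------------------------------------

def parcel_tests(map_values: np.ndarray | VertexField, parcellation: np.ndarray,
                 surrogates: np.ndarray, alpha: float = 0.05,
                 min_vertices: int = 10) -> dict:
    """Region-level inference of a surface map against surrogate nulls.

    Per region: the mean map value, a two-sided permutation p against the
    surrogate distribution of that region's mean, and BY-corrected q-values.
    Across regions: Kruskal–Wallis H on the observed map with a
    surrogate-calibrated p (proportion of surrogates with H at least as
    large) and the eta² effect size ``(H - k + 1)/(n - k)``; pairwise
    region rank-sum post-hocs, BY-corrected. Regions with fewer than
    `min_vertices` vertices are excluded with a warning.
    """
    x = map_values.values if isinstance(map_values, VertexField) else \
        np.asarray(map_values, dtype=float)
    parc = np.asarray(parcellation).astype(int)
    regions = [r for r in np.unique(parc) if (parc == r).sum() >= min_vertices]
    dropped = set(np.unique(parc)) - set(regions)
    if dropped:
        warnings.warn(f"regions excluded (< {min_vertices} vertices): {sorted(dropped)}")
    if len(regions) < 2:
        raise ValueError("need at least 2 usable regions")

    groups = [x[parc == r] for r in regions]
    n = sum(len(g) for g in groups)
    k = len(groups)
    H, _ = stats.kruskal(*groups)
    eta2 = float((H - k + 1) / (n - k))

    # surrogate nulls
    surr_means = np.stack([[s[parc == r].mean() for r in regions] for s in surrogates])
    obs_means = np.array([g.mean() for g in groups])
    n_surr = len(surrogates)
    p_region = np.empty(k)
    for i in range(k):
        null = surr_means[:, i]
        p_two = (1 + np.sum(np.abs(null - null.mean()) >= abs(obs_means[i] - null.mean()))) \
            / (1 + n_surr)
        p_region[i] = p_two
    reject_r, q_region = benjamini_yekutieli(p_region, alpha)

    H_null = np.array([stats.kruskal(*[s[parc == r] for r in regions])[0]
                       for s in surrogates])
    p_kw = float((1 + np.sum(H_null >= H)) / (1 + n_surr))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            _, pp = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            rows.append({"region_a": regions[i], "region_b": regions[j], "p": float(pp)})
    posthoc = pd.DataFrame(rows)
    if not posthoc.empty:
        rej, qv = benjamini_yekutieli(posthoc["p"].to_numpy(), alpha)
        posthoc["q"] = qv
        posthoc["significant"] = rej

    region_table = pd.DataFrame({
        "region": regions, "mean": obs_means, "p": p_region, "q": q_region,
        "significant": reject_r,
    })
    return {"regions": region_table, "kruskal_H": float(H), "kruskal_p": p_kw,
            "eta2": eta2, "posthoc": posthoc}


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------

def rmcorr(values: np.ndarray, condition_scale: np.ndarray) -> dict:
    """ANCOVA-based repeated-measures correlation.

    `values` is (n_subjects, n_conditions); `condition_scale` assigns each
    condition a scalar (e.g. habitat complexity). Subject means are removed
    from both variables and the residuals correlated; degrees of freedom are
    ``N - k - 1`` (N observations, k subjects), the CI comes from the Fisher
    z-transform. Zero within-subject variance is flagged as undefined.
    """
    y = np.asarray(values, dtype=float)
    xs = np.asarray(condition_scale, dtype=float)
    if y.ndim != 2 or y.shape[1] != len(xs):
        raise ValueError("values must be (subjects, conditions) matching the scale")
    k, m = y.shape
    if m < 2 or k < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    ry = y - y.mean(axis=1, keepdims=True)
    X = np.broadcast_to(xs, y.shape)
    rx = X - X.mean(axis=1, keepdims=True)
    vy, vx = ry.ravel(), rx.ravel()
    if np.std(vy) < 1e-300 or np.std(vx) < 1e-300:
        return {"r": np.nan, "p": np.nan, "ci": (np.nan, np.nan),
                "df": k * m - k - 1, "undefined": True}
    r = float(np.sum(vx * vy) / np.sqrt(np.sum(vx ** 2) * np.sum(vy ** 2)))
    df = k * m - k - 1
    tstat = r * np.sqrt(df / max(1 - r ** 2, 1e-300))
    p = float(2 * stats.t.sf(abs(tstat), df))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(max(df - 1, 1))
    ci = (float(np.tanh(z - 1.959963984540054 * se)),
          float(np.tanh(z + 1.959963984540054 * se)))
    return {"r": r, "p": p, "ci": ci, "df": df, "undefined": False}


def habitat_scale_estimate(effects: dict[str, np.ndarray]) -> HabitatScale:
    """Place fossorial on the arboreal–terrestrial axis by least squares.

    Arboreal is fixed at 1, terrestrial at 0; the fossorial effect vector is
    projected onto the axis spanned by the other two:
    ``s = (e_f - e_t) . (e_a - e_t) / |e_a - e_t|²`` — negative when
    fossorial lies beyond terrestrial, mirroring gives -1.
    """
    e_a = np.asarray(effects["arboreal"], dtype=float)
    e_t = np.asarray(effects["terrestrial"], dtype=float)
    e_f = np.asarray(effects["fossorial"], dtype=float)
    axis = e_a - e_t
    denom = float(axis @ axis)
    if denom < 1e-300:
        raise ValueError("degenerate habitat effects: arboreal equals terrestrial")
    s = float((e_f - e_t) @ axis / denom)
    if s >= 0.999:
        raise ValueError("fossorial projects onto/beyond arboreal; ordering violated")
    return HabitatScale(arboreal=1.0, terrestrial=0.0, fossorial=min(s, -1e-9))


# ---------------------------------------------------------------------------
# Decoding against a term library
# ---------------------------------------------------------------------------

def decode_map(map_values: np.ndarray | VertexField, library: dict[str, np.ndarray],
               keep_fraction: float = 0.01) -> pd.DataFrame:
    """Correlate a map with every term map and keep the top fraction.

    Pearson r per term; the strongest ``ceil(keep_fraction * N)`` terms are
    returned sorted by descending r, ties broken by term name.
    """
    x = map_values.values if isinstance(map_values, VertexField) else \
        np.asarray(map_values, dtype=float)
    if len(library) == 0:
        raise ValueError("empty term library")
    if np.std(x) < 1e-300:
        raise ValueError("constant map: correlation undefined")
    rows = []
    for name in sorted(library):
        t = np.asarray(library[name], dtype=float)
        if t.shape != x.shape:
            raise ValueError(f"term '{name}' not on the map topology")
        r = float(np.corrcoef(x, t)[0, 1]) if np.std(t) > 0 else 0.0
        rows.append({"term": name, "r": r})
    df = pd.DataFrame(rows)
    n_keep = int(np.ceil(keep_fraction * len(df)))
    df = df.sort_values(["r", "term"], ascending=[False, True], kind="stable")
    return df.head(n_keep).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------

def cluster_trajectories(traj: np.ndarray, k_max: int = 12, seed: int = 0) -> dict:
    """Agglomerative clustering of term trajectories with silhouette selection.

    Rows are term trajectories over timepoints; distance is correlation
    distance, linkage is average; the cluster count maximizes the mean
    silhouette over k = 2..k_max. Deterministic. Identical rows collapse to
    a single cluster with a warning.
    """
    X = np.asarray(traj, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 trajectories over >= 2 timepoints")
    Z = X - X.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    if np.all(sd < 1e-12) or np.allclose(X, X[0]):
        warnings.warn("all trajectories identical: single cluster")
        return {"labels": np.zeros(len(X), dtype=int), "k": 1, "silhouette": np.nan}
    Zn = Z / np.maximum(sd, 1e-12)[:, None]
    C = np.clip(Zn @ Zn.T / X.shape[1], -1, 1)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    link = linkage(squareform(D, checks=False), method="average")
    from sklearn.metrics import silhouette_score
    best = None
    for k in range(2, min(k_max, len(X) - 1) + 1):
        labels = fcluster(link, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        try:
            s = silhouette_score(D, labels, metric="precomputed")
        except ValueError:
            continue
        if best is None or s > best[0]:
            best = (s, k, labels)
    if best is None:
        warnings.warn("silhouette selection failed; single cluster")
        return {"labels": np.zeros(len(X), dtype=int), "k": 1, "silhouette": np.nan}
    s, k, labels = best
    means = np.stack([X[labels == c].mean(axis=0) for c in np.unique(labels)])
    return {"labels": labels - 1, "k": int(k), "silhouette": float(s),
            "cluster_means": means}


# ---------------------------------------------------------------------------
# General inferential battery
# ---------------------------------------------------------------------------

def inferential_suite(data: pd.DataFrame, dv: str, within: str, subject: str,
                      alpha: float = 0.05) -> dict:
    """Repeated-measures battery on long-format data.

    KS normality per condition, Bartlett equal-variance, RANOVA with a
    Mauchly sphericity test (Greenhouse–Geisser correction applied when
    sphericity is rejected), and Games–Howell post-hocs. RANOVA, sphericity
    and Games–Howell are delegated to pingouin; the FDR procedures above are
    first-principles implementations.
    """
    import pingouin as pg
    conditions = sorted(data[within].unique())
    groups = [data.loc[data[within] == c, dv].to_numpy() for c in conditions]
    if min(len(g) for g in groups) < 3:
        raise ValueError("each condition needs >= 3 observations")
    normality = {c: stats.kstest((g - g.mean()) / max(g.std(ddof=1), 1e-12), "norm").pvalue
                 for c, g in zip(conditions, groups)}
    bart = stats.bartlett(*groups)
    spher = pg.sphericity(data, dv=dv, within=within, subject=subject)
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject, correction=True)
    use_gg = (not spher.spher) if hasattr(spher, "spher") else bool(spher[0])
    pcol = "p_GG_corr" if use_gg and "p_GG_corr" in aov.columns else "p_unc"
    gh = pg.pairwise_gameshowell(data=data, dv=dv, between=within)
    return {
        "normality_ks_p": normality,
        "bartlett_p": float(bart.pvalue),
        "mauchly_p": float(spher.pval) if hasattr(spher, "pval") else float(spher[1]),
        "sphericity_ok": not use_gg,
        "ranova": aov,
        "ranova_p": float(aov[pcol].iloc[0]),
        "greenhouse_geisser_used": bool(use_gg),
        "games_howell": gh,
    }
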