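"""Diet and zooplankton community statistics.

Covers the composition machinery of a chick-diet study: relative-abundance /
occurrence-frequency tables, the linear food selection index (LFSI) with its
parametric bootstrap, net-haul densities, summary-statistics t-tests between
years, Calanus species assignment from stage-specific prosome-length
thresholds, Bray-Curtis + Ward community clustering, and Kruskal-Wallis /
pairwise-Wilcoxon habitat comparisons with a compact letter display.

The LFSI for prey taxon i is

    LFSI_i = GP_i - E_i,

the difference between the taxon's mean relative abundance in gular-pouch
(chick meal) loads and in the environment (at-sea hauls); it ranges from -1
to 1 with positive values indicating preference.  Uncertainty comes from a
parametric bootstrap: GP_i* and E_i* are drawn independently from normal
distributions with the observed means and SDs (no truncation to [0, 1]) and
the index recomputed, 10,000 times by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

# ---------------------------------------------------------------------------
# Composition tables


def _ra_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Sample x taxon relative-abundance (%) matrix; zero-total samples are
    dropped with a warning."""
    wide = (samples.pivot_table(index="sample_id", columns="taxon",
                                values="count", aggfunc="sum", fill_value=0))
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        warnings.warn(f"excluding zero-total samples: {bad}")
        wide = wide.loc[totals > 0]
        totals = totals[totals > 0]
    return wide.div(totals, axis=0) * 100.0


def composition_table(samples: pd.DataFrame,
                      group_by=("source", "year", "stratum")) -> pd.DataFrame:
    """Per-group, per-taxon mean +- SD relative abundance (%) and occurrence
    frequency (%).

    ``samples`` is long format (sample_id, source, year, stratum, taxon,
    count).  RA is computed per sample then averaged over the samples of the
    group; OF is the percentage of samples in which the taxon occurs.
    """
    group_by = list(group_by)
    if samples.empty:
        raise ValueError("no samples")
    meta = samples[["sample_id"] + group_by].drop_duplicates().set_index("sample_id")
    out = []
    for key, sub in samples.groupby(group_by, dropna=False):
        ra = _ra_matrix(sub)
        if ra.empty:
            continue
        key = key if isinstance(key, tuple) else (key,)
        for taxon in ra.columns:
            out.append({
                **dict(zip(group_by, key)),
                "taxon": taxon,
                "n_samples": int(len(ra)),
                "ra_mean_pct": float(ra[taxon].mean()),
                "ra_sd_pct": float(ra[taxon].std(ddof=1)) if len(ra) > 1 else 0.0,
                "of_pct": float((ra[taxon] > 0).mean() * 100.0),
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Linear food selection index


@dataclass
class LFSIResult:
    taxon: str
    stratum: str
    gp_mean: float
    env_mean: float
    point: float  # GP_i - E_i
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None


def lfsi(gp_mean: float, gp_sd: float, env_mean: float, env_sd: float,
         n_boot: int = 10_000, alpha: float = 0.05,
         seed: int | None = None, rng: np.random.Generator | None = None,
         taxon: str = "", stratum: str = "") -> LFSIResult:
    """Linear food selection index with parametric bootstrap.

    Inputs are proportions in [0, 1].  The point estimate is
    ``gp_mean - env_mean``; the bootstrap draws GP* ~ N(gp_mean, gp_sd) and
    E* ~ N(env_mean, env_sd) independently and reports the mean, SD and
    percentile confidence interval of the ``n_boot`` index replicates.
    """
    for name, v in (("gp_mean", gp_mean), ("env_mean", env_mean)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1]")
    if gp_sd < 0 or env_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if rng is None:
        if seed is None:
            raise ValueError("supply seed (or rng) for a reproducible bootstrap")
        rng = np.random.default_rng(seed)
    draws = (rng.normal(gp_mean, gp_sd, size=n_boot)
             - rng.normal(env_mean, env_sd, size=n_boot))
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return LFSIResult(taxon=taxon, stratum=stratum,
                      gp_mean=float(gp_mean), env_mean=float(env_mean),
                      point=float(gp_mean - env_mean),
                      boot_mean=float(draws.mean()),
                      boot_sd=float(draws.std(ddof=1)),
                      ci_low=float(lo), ci_high=float(hi),
                      n_boot=int(n_boot), seed=seed)


def lfsi_table(pouch_samples: pd.DataFrame, env_samples: pd.DataFrame,
               n_boot: int = 10_000, alpha: float = 0.05,
               seed: int = 0) -> pd.DataFrame:
    """Per-taxon, per-stratum LFSI from raw count tables.

    Group means/SDs of per-sample relative abundances feed the bootstrap;
    the diet side pools the supplied pouch samples, the environment side is
    computed separately for each at-sea stratum.
    """
    gp = composition_table(pouch_samples, group_by=["source"])
    env = composition_table(env_samples, group_by=["stratum"])
    taxa = sorted(set(gp.taxon) | set(env.taxon))
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, esub in env.groupby("stratum"):
        e = esub.set_index("taxon")
        g = gp.set_index("taxon")
        for taxon in taxa:
            gm = g.ra_mean_pct.get(taxon, 0.0) / 100.0
            gs = g.ra_sd_pct.get(taxon, 0.0) / 100.0
            em = e.ra_mean_pct.get(taxon, 0.0) / 100.0
            es = e.ra_sd_pct.get(taxon, 0.0) / 100.0
            res = lfsi(gm, gs, em, es, n_boot=n_boot, alpha=alpha, rng=rng,
                       taxon=taxon, stratum=str(stratum))
            rows.append(vars(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Densities and summary t-tests


def density_per_m3(count, haul_depth_m: float = 50.0,
                   net_diameter_m: float = 0.57):
    """Individuals per m^3 from a vertical net haul, assuming 100%
    filtration: count / (pi * (d/2)^2 * depth)."""
    if haul_depth_m <= 0 or net_diameter_m <= 0:
        raise ValueError("haul depth and net diameter must be positive")
    volume = np.pi * (net_diameter_m / 2.0) ** 2 * haul_depth_m
    return np.asarray(count, dtype=float) / volume


def two_sample_t_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> dict:
    """Pooled-variance two-sample Student's t-test from summary statistics.

    t = (mean1 - mean2) / (sp * sqrt(1/n1 + 1/n2)) with the pooled variance
    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2); two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ValueError("t undefined: both SDs zero and means equal")
        return {"t": np.inf if mean1 > mean2 else -np.inf,
                "df": n1 + n2 - 2, "p": 0.0}
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


# ---------------------------------------------------------------------------
# Calanus species from prosome length

CALANUS_SPECIES = ("finmarchicus", "glacialis", "hyperboreus")


@dataclass(frozen=True)
class CalanusSizeRule:
    """Stage-specific prosome-length cut-points (mm) separating the three
    Calanus species, smallest to largest."""

    stage: str
    cutpoints: tuple[float, float]

    def __post_init__(self):
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cut-points must be strictly increasing")


# Assumed default thresholds (synthetic placeholders in the plausible range
# for the three species; real analyses should fit thresholds to their own
# length distributions with `suggest_cutpoints`).
DEFAULT_CALANUS_RULES = {
    "CIV": CalanusSizeRule("CIV", (1.8, 2.8)),
    "CV": CalanusSizeRule("CV", (2.9, 4.0)),
    "adult": CalanusSizeRule("adult", (3.3, 4.6)),
}


def classify_calanus(stage: str, prosome_length_mm,
                     rules: dict[str, CalanusSizeRule] | None = None):
    """Assign Calanus species from stage and prosome length.

    A length exactly on a cut-point goes to the larger species.  A stage
    with no rule yields ``"unclassified"`` with a warning.
    """
    rules = DEFAULT_CALANUS_RULES if rules is None else rules
    rule = rules.get(stage)
    lengths = np.asarray(prosome_length_mm, dtype=float)
    scalar = lengths.ndim == 0
    lengths = np.atleast_1d(lengths)
    if rule is None:
        warnings.warn(f"no size rule for stage {stage!r}; unclassified")
        out = np.array(["unclassified"] * lengths.size, dtype=object)
    else:
        idx = np.searchsorted(np.asarray(rule.cutpoints), lengths, side="right")
        out = np.array(CALANUS_SPECIES, dtype=object)[idx]
    return out[0] if scalar else out


def suggest_cutpoints(lengths, n_species: int = 3,
                      grid_size: int = 512) -> tuple[float, ...]:
    """Data-driven cut-points: the deepest local minima of a Gaussian KDE of
    the pooled length distribution (one fewer than the number of species)."""
    lengths = np.asarray(lengths, dtype=float)
    kde = stats.gaussian_kde(lengths)
    grid = np.linspace(lengths.min(), lengths.max(), grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])) + 1
    if len(interior) < n_species - 1:
        raise ValueError("length distribution has too few modes for "
                         f"{n_species} species")
    deepest = interior[np.argsort(dens[interior])][: n_species - 1]
    return tuple(sorted(float(grid[i]) for i in deepest))


# ---------------------------------------------------------------------------
# Community clustering


def bray_curtis_ward(samples: pd.DataFrame, k: int | None = None,
                     use_relative: bool = False,
                     variant: str = "ward.D2"):
    """Bray-Curtis dissimilarities and Ward agglomeration of samples.

    ``samples`` is the long count format; rows of all zeros are excluded.
    ``variant`` selects the classic minimum-variance recursion on squared
    dissimilarities (``"ward.D2"``, default) or the historical recursion on
    the raw dissimilarities (``"ward.D"``) — group recovery can differ
    between the two.  Returns ``(distance_df, linkage, labels)``; labels are
    None unless ``k`` is given.
    """
    wide = (samples.pivot_table(index="sample_id", columns="taxon",
                                values="count", aggfunc="sum", fill_value=0))
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(f"excluding all-zero samples: {list(totals.index[totals == 0])}")
        wide = wide.loc[totals > 0]
    if len(wide) < 2:
        raise ValueError("need at least two non-empty samples")
    mat = wide.to_numpy(dtype=float)
    if use_relative:
        mat = mat / mat.sum(axis=1, keepdims=True)
    cond = pdist(mat, metric="braycurtis")
    dist_df = pd.DataFrame(squareform(cond), index=wide.index, columns=wide.index)
    if variant == "ward.D2":
        Z = hierarchy.linkage(cond, method="ward")
    elif variant == "ward.D":
        # the classic recursion on raw d: run the D2 machinery on sqrt(d)
        # and square the merge heights back
        Z = hierarchy.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError("variant must be 'ward.D2' or 'ward.D'")
    labels = None
    if k is not None:
        labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"),
                           index=wide.index, name="cluster")
    return dist_df, Z, labels


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# Habitat comparisons


def _compact_letters(groups: list, nsd: set[frozenset]) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different.  Letters come from the maximal cliques of the
    not-significantly-different graph (fine for the handful of habitat
    strata this is used with)."""
    if len(groups) > 12:
        raise ValueError("compact letter display limited to 12 groups")
    cliques = []
    for r in range(len(groups), 0, -1):
        for comb in itertools.combinations(groups, r):
            if any(set(comb) <= c for c in cliques):
                continue
            if all(frozenset((a, b)) in nsd
                   for a, b in itertools.combinations(comb, 2)):
                cliques.append(set(comb))
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijkl", cliques):
        for g in groups:
            if g in clique:
                letters[g] += letter
    return letters


def habitat_density_compare(df: pd.DataFrame, value_col: str = "density",
                            group_col: str = "stratum",
                            species_col: str | None = "species",
                            alpha: float = 0.01) -> dict:
    """Kruskal-Wallis across habitat strata with pairwise Wilcoxon letters.

    ``df`` holds one density observation per sample; when ``species_col`` is
    present the analysis runs per species.  Strata with fewer than two
    samples are excluded with a warning.  Returns, per species, the
    tie-corrected H and p, the pairwise two-sided p-value table and a
    compact letter display at ``alpha`` (strata sorted by descending median;
    shared letters mean not significantly different).
    """
    results = {}
    species_iter = (df.groupby(species_col) if species_col and species_col in df.columns
                    else [("all", df)])
    for sp, sub in species_iter:
        groups, names = [], []
        for g, vals in sub.groupby(group_col):
            v = vals[value_col].dropna().to_numpy()
            if len(v) < 2:
                warnings.warn(f"stratum {g!r} has fewer than 2 samples; excluded")
                continue
            groups.append(v)
            names.append(g)
        if len(groups) < 2:
            raise ValueError("need at least two strata with >= 2 samples")
        if np.ptp(np.concatenate(groups)) == 0:
            H, p = 0.0, 1.0  # all observations identical: no evidence by convention
        else:
            H, p = stats.kruskal(*groups)
        order = [names[i] for i in
                 np.argsort([-np.median(g) for g in groups], kind="stable")]
        pairwise = pd.DataFrame(np.nan, index=names, columns=names)
        nsd = set()
        for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
            pw = stats.mannwhitneyu(groups[i], groups[j],
                                    alternative="two-sided").pvalue
            pairwise.loc[a, b] = pairwise.loc[b, a] = pw
            if pw >= alpha:
                nsd.add(frozenset((a, b)))
        letters = _compact_letters(order, nsd)
        results[sp] = {"H": float(H), "p": float(p), "pairwise_p": pairwise,
                       "letters": letters, "alpha": alpha}
    return results
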