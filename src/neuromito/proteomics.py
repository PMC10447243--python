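"""Label-free quantification (LFQ) proteomics processing.

The stage mirrors a standard neural-tissue LFQ workflow: technical
replicates are averaged, missing values are imputed in two tiers, sample
similarity is checked by PCA, and per-protein differential abundance is
tested with an equal-variance Student's t-test under Bonferroni control of
the family-wise error rate.

The two imputation tiers address the two missingness mechanisms of LFQ
data.  Proteins detected in fewer than half the samples of an experimental
group are treated as left-censored (below the instrument's detection limit)
in that group: *all* of the group's values are replaced by draws from a
down-shifted narrow Gaussian, ``Normal(mu_all - 2*sd_all, (0.3*sd_all)^2)``
where ``mu_all``/``sd_all`` are the mean and standard deviation of every
observed log2 intensity in the dataset.  Remaining sporadic missing values
are assumed recoverable from the correlation structure across samples and
are filled by multiple imputation by chained equations (per-sample linear
regressions on all other samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from neuromito import io as _io

Scale = Literal["linear", "log2"]

TIER_NONE = "none"
TIER_SHIFTED = "shifted_gaussian"
TIER_CHAINED = "chained"


@dataclass
class LfqMatrix:
    """Protein x sample intensity matrix with sample design metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein id, one column per sample; missing
        values are NaN.
    design
        DataFrame indexed by sample id with columns ``group`` (e.g.
        ``control`` / ``case``) and ``biosample`` (the biological sample a
        technical replicate belongs to).
    scale
        Whether intensities are raw (``linear``) or log2-transformed.
    """

    intensities: pd.DataFrame
    design: pd.DataFrame
    scale: Scale = "linear"

    def __post_init__(self) -> None:
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if "group" not in self.design.columns:
            raise ValueError("design must have a 'group' column")
        if "biosample" not in self.design.columns:
            self.design = self.design.copy()
            self.design["biosample"] = self.design.index
        if self.scale == "linear" and (self.intensities < 0).any().any():
            raise ValueError("negative linear intensities")

    # -- convenience accessors -------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def groups(self) -> pd.Series:
        """Group label per sample column, in column order."""
        return self.design.loc[self.intensities.columns, "group"]

    def samples_of(self, group: str) -> list[str]:
        g = self.groups()
        return [s for s in self.intensities.columns if g[s] == group]

    def log2(self) -> "LfqMatrix":
        """Return a log2-scale copy (no-op if already log2)."""
        if self.scale == "log2":
            return self
        vals = self.intensities.where(self.intensities > 0)
        return LfqMatrix(np.log2(vals), self.design, scale="log2")

    @classmethod
    def from_protein_groups(cls, matrix_path, design_path) -> "LfqMatrix":
        """Load from a proteinGroups TSV plus a design TSV."""
        mat = _io.read_protein_groups(matrix_path)
        design = _io.read_design(design_path)
        return cls(mat, design, scale="linear")


@dataclass
class AnnotationTable:
    """Per-protein annotation: mitochondrial membership, sub-mitochondrial
    location, pathway sets, genome of origin and (optional) half-life."""

    table: pd.DataFrame

    LOCATIONS = ("matrix", "IMM", "OMM", "IMS", "unknown")

    def __post_init__(self) -> None:
        if "pathways" not in self.table.columns:
            raise ValueError("annotation table needs a 'pathways' column")

    def pathway_sets(self) -> dict[str, set[str]]:
        """Invert the per-protein pathway column into pathway -> protein set."""
        out: dict[str, set[str]] = {}
        for pid, pw in self.table["pathways"].items():
            members = pw if isinstance(pw, (set, frozenset)) else _split(pw)
            for p in members:
                out.setdefault(p, set()).add(pid)
        return out

    def to_tsv(self, path) -> None:
        tab = self.table.copy()
        tab["pathways"] = [
            ";".join(sorted(p)) if isinstance(p, (set, frozenset)) else p
            for p in tab["pathways"]
        ]
        tab.to_csv(path, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        tab = pd.read_csv(path, sep="\t", index_col="protein_id")
        tab["pathways"] = [frozenset(_split(p)) for p in tab["pathways"].fillna("")]
        return cls(tab)


def _split(s: str) -> set[str]:
    return {p for p in str(s).split(";") if p and p != "nan"}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def average_technical_replicates(m: LfqMatrix) -> LfqMatrix:
    """Collapse technical replicates to one column per biological sample.

    A cell becomes the mean of the non-missing replicate values; a cell
    whose replicates are all missing stays missing.  Replicate groups that
    span different experimental groups are rejected.
    """
    design = m.design.loc[m.intensities.columns]
    by_bio = design.groupby("biosample", sort=False)
    for bio, sub in by_bio:
        if sub["group"].nunique() > 1:
            raise ValueError(
                f"technical replicates of {bio!r} span groups "
                f"{sorted(sub['group'].unique())}"
            )
    cols = {}
    rows = []
    for bio, sub in by_bio:
        cols[bio] = m.intensities[sub.index].mean(axis=1, skipna=True)
        rows.append({"sample": bio, "group": sub["group"].iloc[0], "biosample": bio})
    averaged = pd.DataFrame(cols)
    new_design = pd.DataFrame(rows).set_index("sample")
    return LfqMatrix(averaged, new_design, scale=m.scale)


def impute(
    m: LfqMatrix,
    *,
    shift_sd: float = 2.0,
    width_sd: float = 0.3,
    detect_fraction: float = 0.5,
    overwrite_observed: bool = True,
    mice_iterations: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[LfqMatrix, pd.DataFrame]:
    """Two-tier imputation of missing log2 LFQ intensities.

    Tier 1 (left-censored): any protein detected in fewer than
    ``detect_fraction`` of the samples of at least one group has that
    group's values replaced by draws from
    ``Normal(mu_all - shift_sd*sd_all, (width_sd*sd_all)^2)``; with the
    default ``overwrite_observed=True`` the group's observed values are
    overwritten too, treating the whole group as below detection.

    Tier 2 (sporadic): remaining missing cells are filled by chained
    equations — iterated per-sample linear regressions on all other
    samples (``sklearn`` ``IterativeImputer``).

    Returns the fully imputed matrix and a same-shaped tier map with values
    ``none`` / ``shifted_gaussian`` / ``chained`` per cell.
    """
    if m.scale != "log2":
        raise ValueError("impute expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    vals = m.intensities.copy()
    observed = vals.notna()
    flat = vals.values[observed.values]
    if flat.size == 0:
        raise ValueError("matrix has no observed values")
    mu_all = float(np.mean(flat))
    sd_all = float(np.std(flat, ddof=1))
    if sd_all == 0:
        raise ValueError("degenerate dataset: zero variance of observed values")

    for group in m.groups().unique():
        samples = m.samples_of(group)
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has <2 samples")

    tier = pd.DataFrame(
        TIER_NONE, index=vals.index, columns=vals.columns, dtype=object
    )

    # tier 1: whole-group left-censored replacement
    for group in m.groups().unique():
        samples = m.samples_of(group)
        detected = observed[samples].sum(axis=1) / len(samples)
        censored = detected < detect_fraction
        target = vals.index[censored]
        if len(target) == 0:
            continue
        block = rng.normal(
            mu_all - shift_sd * sd_all,
            width_sd * sd_all,
            size=(len(target), len(samples)),
        )
        if overwrite_observed:
            vals.loc[target, samples] = block
            tier.loc[target, samples] = TIER_SHIFTED
        else:
            mask = ~observed.loc[target, samples]
            sub = vals.loc[target, samples].where(~mask, block)
            vals.loc[target, samples] = sub
            tsub = tier.loc[target, samples].where(~mask, TIER_SHIFTED)
            tier.loc[target, samples] = tsub

    # tier 2: chained-equation regression across samples
    still_missing = vals.isna()
    if still_missing.any().any():
        # lazy import: sklearn gates this estimator behind an opt-in module
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imputer = IterativeImputer(
            max_iter=mice_iterations,
            random_state=int(rng.integers(2**31 - 1)),
            sample_posterior=False,
            keep_empty_features=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = imputer.fit_transform(vals.values)
        vals = pd.DataFrame(filled, index=vals.index, columns=vals.columns)
        tier = tier.where(~still_missing, TIER_CHAINED)

    assert not vals.isna().any().any()
    return LfqMatrix(vals, m.design, scale="log2"), tier


def pca_qc(
    m: LfqMatrix, *, n_components: int = 2, mad_threshold: float = 3.0
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """PCA over samples (proteins as features) for quality control.

    Returns per-sample coordinates on the first two components, the
    explained-variance fractions, and a boolean outlier flag per sample.
    A sample is flagged when its distance from the centroid in the
    component-scaled PC1-2 plane has a modified z-score (median/MAD rule)
    above ``mad_threshold``.  Removal is the caller's choice.
    """
    from sklearn.decomposition import PCA

    X = m.intensities.T.values  # samples x proteins
    if X.shape[0] < 3:
        raise ValueError("pca_qc needs at least 3 samples")
    if np.isnan(X).any():
        raise ValueError("pca_qc expects an imputed (complete) matrix")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X - X.mean(axis=0))
    evr = pca.explained_variance_ratio_
    # scale each axis by its spread so both components weigh equally
    scale = coords.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    dist = np.sqrt(((coords / scale) ** 2).sum(axis=1))
    med = np.median(dist)
    mad = np.median(np.abs(dist - med)) * 1.4826
    if mad == 0:
        flags = np.zeros(len(dist), dtype=bool)
    else:
        flags = (dist - med) / mad > mad_threshold
    coord_df = pd.DataFrame(
        coords, index=m.intensities.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return coord_df, evr, pd.Series(flags, index=m.intensities.columns)


def differential_abundance(
    m: LfqMatrix,
    *,
    case: str = "case",
    control: str = "control",
    tier_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-protein differential abundance between two groups.

    Equal-variance two-sided Student's t-test on log2 intensities, with
    ``log2fc = mean(case) - mean(control)`` and Bonferroni-corrected
    p-values ``p_bonf = min(1, m * p_raw)`` over the m tested proteins.
    """
    if m.scale != "log2":
        raise ValueError("differential_abundance expects a log2-scale matrix")
    case_s = m.samples_of(case)
    ctrl_s = m.samples_of(control)
    if len(case_s) < 2 or len(ctrl_s) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = m.intensities[case_s].values
    B = m.intensities[ctrl_s].values
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("differential_abundance expects an imputed matrix")
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    n_tests = len(m.protein_ids)
    out = pd.DataFrame(
        {
            "log2fc": A.mean(axis=1) - B.mean(axis=1),
            "t_stat": t,
            "p_raw": p,
            "p_bonf": np.minimum(1.0, p * n_tests),
            "n_case_obs": len(case_s),
            "n_control_obs": len(ctrl_s),
        },
        index=m.protein_ids,
    )
    if tier_map is not None:
        # a protein's tier is the strongest mechanism applied to any cell
        order = {TIER_NONE: 0, TIER_CHAINED: 1, TIER_SHIFTED: 2}
        inv = {v: k for k, v in order.items()}
        worst = tier_map.apply(lambda r: inv[max(order[c] for c in r)], axis=1)
        out["imputation_tier"] = worst
    return out


def complex_level_anova(
    m: LfqMatrix, membership: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """One-way ANOVA across groups on per-sample mean LFQ of each complex.

    For every complex (e.g. a respiratory-chain complex), each sample is
    summarised as the mean LFQ of member proteins; the group means of these
    summaries are then compared by one-way ANOVA.
    """
    groups = m.groups()
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("complex_level_anova needs at least two groups")
    rows = []
    for name, proteins in membership.items():
        present = [p for p in proteins if p in m.intensities.index]
        if not present:
            warnings.warn(f"complex {name!r} has no measured proteins; skipped")
            continue
        per_sample = m.intensities.loc[present].mean(axis=0)
        arrays = [per_sample[groups[groups == g].index].values for g in labels]
        F, p = stats.f_oneway(*arrays)
        rows.append({"complex": name, "F": F, "p": p, "n_proteins": len(present)})
    return pd.DataFrame(rows).set_index("complex")


def rank_by_log2fc(
    diff: pd.DataFrame,
    annot: AnnotationTable | None = None,
    pathway_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Rank proteins ascending by log2 fold change (1 = most depleted).

    Ties are broken by lexicographic protein id so output is deterministic.
    One boolean flag column is added per requested pathway.
    """
    ranked = diff.sort_index().sort_values("log2fc", kind="mergesort").copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if annot is not None:
        sets = annot.pathway_sets()
        for pid in pathway_ids:
            members = sets.get(pid, set())
            ranked[f"in_{pid}"] = [p in members for p in ranked.index]
    return ranked


def correlate_external(
    diff: pd.DataFrame,
    external: Mapping[str, float] | pd.Series,
    *,
    method: Literal["pearson", "spearman"] = "pearson",
    column: str = "log2fc",
) -> dict[str, float]:
    """Correlate per-protein statistics with an external per-protein value
    (e.g. translatome fold changes or protein half-lives).

    Returns ``{"r", "p", "n"}`` over the protein intersection (>= 3 needed).
    """
    ext = pd.Series(external, dtype=float).dropna()
    shared = diff.index.intersection(ext.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} overlapping proteins (need >= 3)")
    x = diff.loc[shared, column].values
    y = ext[shared].values
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": int(len(shared))}
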