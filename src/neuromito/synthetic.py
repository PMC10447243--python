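"""Seeded generators for every input the pipeline consumes.

The generators reproduce the statistical structure the analysis stages
assume, so the whole pipeline is testable without any raw data download:

* ``simulate_lfq`` — log-normal LFQ intensities with planted group effects,
  left-censored (intensity-dependent) missingness, and technical replicate
  pairs; the default design mirrors an acute-disease cohort of six control
  and five case animals.
* ``simulate_biosensor_stack`` — two-channel volumes with axon-shaped ROIs
  of known true ratio, plus background, optional FRET crosstalk and noise.
* ``simulate_organelle_table`` — single-organelle morphology and ratio
  measurements with stage-dependent shifts.
* ``simulate_abundance_profile`` — enzyme-abundance scale factors
  (sample / control mean) for the kinetic model.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from neuromito.biosensor import ImageStack
from neuromito.proteomics import AnnotationTable, LfqMatrix

#: proteins used for the default pathway structure; the TCA / ETC sets
#: match the enzymes mapped by the kinetic model.
DEFAULT_TCA = ("Idh3a", "Idh3b", "Idh3g", "Ogdh", "Sdha", "Mdh2")
DEFAULT_ETC = ("Ndufs1", "Ndufv1", "Sdhb", "Uqcrc1", "Uqcrc2", "Cox4i1",
               "Cox5a", "Atp5f1a", "Atp5f1b")


@dataclass
class SimDesign:
    """Design of a simulated LFQ cohort.

    Defaults emulate an acute cohort: 6 control vs 5 case biological
    samples, two technical replicates each, ~2,000 protein groups with
    log2 intensities around 25 +- 2.
    """

    n_control: int = 6
    n_case: int = 5
    n_tech_reps: int = 2
    n_proteins: int = 2000
    pathways: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effect_log2fc: dict[str, float] = field(default_factory=dict)
    base_mean_log2: float = 25.0
    base_sd_log2: float = 2.0
    bio_sd_log2: float = 0.4
    tech_sd_log2: float = 0.1
    censor_quantile: float = 0.0
    censor_prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need >= 2 biological samples per group")
        if self.n_tech_reps < 1:
            raise ValueError("n_tech_reps must be >= 1")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must be in [0, 1)")
        universe = set(self.protein_ids())
        for pw, members in self.pathways.items():
            stray = set(members) - universe
            if stray:
                raise ValueError(f"pathway {pw!r} has unknown proteins: {sorted(stray)}")

    def protein_ids(self) -> list[str]:
        named = [p for members in self.pathways.values() for p in members]
        named = list(dict.fromkeys(named))  # preserve order, deduplicate
        n_anon = self.n_proteins - len(named)
        if n_anon < 0:
            raise ValueError("more pathway proteins than n_proteins")
        return named + [f"P{i:05d}" for i in range(n_anon)]


def default_design(**overrides) -> SimDesign:
    """A ready-made design with TCA/ETC pathway structure and a planted
    -1.0 log2 fold change on the TCA set (the down-regulation the study
    conditions emulate)."""
    pathways = {"TCA": DEFAULT_TCA, "ETC": DEFAULT_ETC}
    effects = {p: -1.0 for p in DEFAULT_TCA}
    effects.update({p: -0.5 for p in DEFAULT_ETC})
    kwargs = dict(pathways=pathways, effect_log2fc=effects)
    kwargs.update(overrides)
    return SimDesign(**kwargs)


def simulate_lfq(
    design: SimDesign,
) -> tuple[LfqMatrix, AnnotationTable, pd.DataFrame]:
    """Simulate an LFQ cohort with planted effects and MNAR missingness.

    Per protein, log2 intensity is protein-specific location (drawn from
    ``Normal(base_mean_log2, base_sd_log2)``) plus the planted group
    effect, biological noise per biosample and technical noise per
    replicate.  Censoring removes values below each sample's
    ``censor_quantile`` intensity threshold with probability
    ``censor_prob``, making missingness intensity-dependent by
    construction.

    Returns the linear-scale matrix (technical replicates as separate
    columns), an annotation table, and the truth table of planted log2
    fold changes.
    """
    rng = np.random.default_rng(design.seed)
    proteins = design.protein_ids()
    n_prot = len(proteins)

    biosamples = [f"control_{i+1}" for i in range(design.n_control)] + [
        f"case_{i+1}" for i in range(design.n_case)
    ]
    groups = ["control"] * design.n_control + ["case"] * design.n_case

    protein_loc = rng.normal(design.base_mean_log2, design.base_sd_log2, n_prot)
    effects = np.array(
        [design.effect_log2fc.get(p, 0.0) for p in proteins]
    )

    cols: dict[str, np.ndarray] = {}
    rows_design = []
    for bio, grp in zip(biosamples, groups):
        base = (
            protein_loc
            + (effects if grp == "case" else 0.0)
            + rng.normal(0.0, design.bio_sd_log2, n_prot)
        )
        for r in range(design.n_tech_reps):
            name = f"{bio}_r{r+1}" if design.n_tech_reps > 1 else bio
            cols[name] = base + rng.normal(0.0, design.tech_sd_log2, n_prot)
            rows_design.append({"sample": name, "group": grp, "biosample": bio})

    log2 = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))

    # left-censoring: per-sample intensity threshold + Bernoulli jitter
    if design.censor_quantile > 0:
        for col in log2.columns:
            thr = log2[col].quantile(design.censor_quantile)
            below = log2[col] < thr
            drop = below & (rng.random(n_prot) < design.censor_prob)
            log2.loc[drop, col] = np.nan

    linear = np.power(2.0, log2)
    design_df = pd.DataFrame(rows_design).set_index("sample")
    matrix = LfqMatrix(linear, design_df, scale="linear")

    annot = _default_annotation(proteins, design.pathways, rng)
    truth = pd.DataFrame(
        {"planted_log2fc": effects}, index=pd.Index(proteins, name="protein_id")
    )
    truth["in_pathway"] = [
        ";".join(sorted(pw for pw, mem in design.pathways.items() if p in mem))
        for p in proteins
    ]
    return matrix, annot, truth


def _default_annotation(
    proteins: Sequence[str],
    pathways: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
) -> AnnotationTable:
    in_pathway = {p for mem in pathways.values() for p in mem}
    locations = np.array(["matrix", "IMM", "OMM", "IMS", "unknown"])
    rows = []
    for p in proteins:
        is_mito = p in in_pathway or rng.random() < 0.3
        rows.append(
            {
                "is_mito": is_mito,
                "submito_location": (
                    rng.choice(locations) if is_mito else "unknown"
                ),
                "pathways": frozenset(
                    pw for pw, mem in pathways.items() if p in mem
                ),
                "genome": "mtDNA" if (is_mito and rng.random() < 0.05) else "nuclear",
                "half_life_days": float(rng.lognormal(2.0, 0.5)),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(proteins, name="protein_id"))
    return AnnotationTable(table)


@dataclass
class SimImagingDesign:
    """Design of a simulated two-channel biosensor volume."""

    n_axons: int = 20
    stage_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    true_ratio_by_stage: tuple[float, float, float] = (1.0, 0.8, 0.6)
    background_per_channel: tuple[float, float] = (0.0, 0.0)
    crosstalk_alpha: float = 0.0
    noise_sd: float = 0.0
    stack_shape: tuple[int, int, int] = (4, 64, 128)
    axon_width_px: int = 3
    axon_gap_px: int = 2
    signal_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.stage_probs), 1.0):
            raise ValueError("stage_probs must sum to 1")
        if any(r <= 0 for r in self.true_ratio_by_stage):
            raise ValueError("true ratios must be > 0")
        if not 0 <= self.crosstalk_alpha < 1:
            raise ValueError("crosstalk_alpha must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_biosensor_stack(
    design: SimImagingDesign, *, fret_mode: bool = False
) -> tuple[ImageStack, pd.DataFrame]:
    """Paint axon tubes with known true ratios into a two-channel volume.

    Axons are straight tubes along x, each ``axon_width_px`` rows tall,
    placed in one z plane.  The denominator (donor) channel carries
    ``signal_level`` inside axons; the numerator (acceptor) channel
    carries ``true_ratio x signal_level`` — plus, in FRET mode,
    ``crosstalk_alpha x`` the donor signal.  Per-channel backgrounds are
    added everywhere, then Gaussian noise, then clipping at zero.

    Returns the stack (channel 0 = numerator/acceptor, channel 1 =
    denominator/donor) and the ground-truth axon table.
    """
    rng = np.random.default_rng(design.seed)
    z, y, x = design.stack_shape
    slot = design.axon_width_px + design.axon_gap_px
    per_plane = max(0, (y - design.axon_gap_px) // slot)
    capacity = per_plane * z
    if design.n_axons > capacity:
        raise ValueError(
            f"stack of shape {design.stack_shape} fits at most {capacity} axons "
            f"of width {design.axon_width_px}px with {design.axon_gap_px}px gaps; "
            f"{design.n_axons} requested"
        )

    mask = np.zeros((z, y, x), dtype=np.int32)
    num = np.zeros((z, y, x))
    den = np.zeros((z, y, x))
    stages = rng.choice(3, size=design.n_axons, p=design.stage_probs)
    truth_rows = []
    for k in range(design.n_axons):
        plane = k // per_plane
        y0 = design.axon_gap_px + (k % per_plane) * slot
        stage = int(stages[k])
        ratio = design.true_ratio_by_stage[stage]
        axon_id = k + 1
        mask[plane, y0:y0 + design.axon_width_px, :] = axon_id
        den[plane, y0:y0 + design.axon_width_px, :] = design.signal_level
        sig = ratio * design.signal_level
        if fret_mode:
            sig += design.crosstalk_alpha * design.signal_level
        num[plane, y0:y0 + design.axon_width_px, :] = sig
        truth_rows.append(
            {"axon_id": axon_id, "stage": stage, "true_ratio": ratio,
             "z": plane, "y0": y0}
        )

    bg_num, bg_den = design.background_per_channel
    num = num + bg_num
    den = den + bg_den
    if design.noise_sd > 0:
        num = num + rng.normal(0.0, design.noise_sd, num.shape)
        den = den + rng.normal(0.0, design.noise_sd, den.shape)
    data = np.clip(np.stack([num, den]), 0.0, None)
    names = ("acceptor", "donor") if fret_mode else ("numerator", "denominator")
    stack = ImageStack(data, mask, channel_names=names)
    return stack, pd.DataFrame(truth_rows).set_index("axon_id")


def simulate_organelle_table(
    n_per_stage: Mapping[int, int],
    *,
    ratio_mean_by_stage: Mapping[int, float],
    ratio_sd_by_stage: Mapping[int, float],
    shape_log_mean_by_stage: Mapping[int, float] | None = None,
    shape_log_sd: float = 0.3,
    signal_level: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-organelle measurements with stage-dependent shifts.

    Per organelle: stage, ratio (Gaussian per stage), length and width
    (log-normal; the shape factor length/width falls with stage when so
    configured, emulating mitochondrial rounding during degeneration) and
    the two channel intensities consistent with the drawn ratio.
    """
    rng = np.random.default_rng(seed)
    if shape_log_mean_by_stage is None:
        shape_log_mean_by_stage = {0: np.log(3.0), 1: np.log(2.0), 2: np.log(1.2)}
    for stage, n in n_per_stage.items():
        if n < 1:
            raise ValueError(f"stage {stage}: n must be >= 1")
        if ratio_sd_by_stage[stage] < 0:
            raise ValueError("ratio sd must be >= 0")
    rows = []
    oid = 0
    for stage in sorted(n_per_stage):
        n = n_per_stage[stage]
        ratios = rng.normal(
            ratio_mean_by_stage[stage], ratio_sd_by_stage[stage], n
        )
        shape = np.exp(rng.normal(shape_log_mean_by_stage[stage], shape_log_sd, n))
        width = np.exp(rng.normal(np.log(0.4), 0.15, n))  # um
        for i in range(n):
            oid += 1
            rows.append(
                {
                    "organelle_id": oid,
                    "axon_id": (oid - 1) // 10 + 1,
                    "stage": stage,
                    "length_um": shape[i] * width[i],
                    "width_um": width[i],
                    "shape_factor": shape[i],
                    "ch_den": signal_level,
                    "ch_num": ratios[i] * signal_level,
                    "ratio": ratios[i],
                }
            )
    return pd.DataFrame(rows).set_index("organelle_id")


def simulate_abundance_profile(
    downreg: Mapping[str, float],
    *,
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Relative enzyme abundances E(sample)/E(mean control).

    ``downreg`` maps enzyme id to its true scale factor; optional
    multiplicative log-normal noise (``exp(Normal(0, noise_sd_log))``)
    emulates measurement scatter, so the geometric mean over draws equals
    the factor.
    """
    rng = np.random.default_rng(seed)
    factors = pd.Series(downreg, dtype=float)
    if (factors <= 0).any():
        raise ValueError("abundance factors must be > 0")
    if noise_sd_log > 0:
        factors = factors * np.exp(rng.normal(0.0, noise_sd_log, len(factors)))
    factors.index.name = "enzyme"
    factors.name = "relative_abundance"
    return factors
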