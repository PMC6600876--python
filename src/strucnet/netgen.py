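"""Synthetic parcellations, expression maps and matched case/control cohorts.

This module emulates the statistical structure of a two-group diffusion-MRI
connectome study so that every downstream stage (network construction,
graph metrics, threshold-sweep group statistics, expression regression) can
be exercised against a known planted truth:

* an 85-region parcellation (34 cortical regions per hemisphere in the
  Desikan-Killiany naming scheme plus 17 subcortical structures);
* per-subject streamline-count and mean-FA matrices whose control-group
  edge weights have anatomical-class-specific means (subcortical-cortical,
  left-hemispheric, right-hemispheric, interhemispheric);
* a case group whose counts and FA weights are attenuated by a global
  multiplicative factor and, optionally, by an additional nodal factor
  coupled to a synthetic regional gene-expression map;
* multi-donor expression tables with a left > right hemispheric gradient.

Nothing voxel- or streamline-level is simulated: matrices are drawn
directly at the region-pair level, edges independent given their class
mean (the only between-subject covariance a desk-scale emulation can
justify).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Region",
    "Parcellation",
    "ExpressionProfile",
    "SyntheticSpec",
    "Subject",
    "SubjectPair",
    "Cohort",
    "PlantedTruth",
    "DK_CORTICAL_34",
    "SUBCORTICAL_17",
    "generate_parcellation",
    "default_parcellation",
    "generate_expression_map",
    "generate_cohort",
    "planted_truth",
]

#: The 34 cortical region names of the Desikan-Killiany atlas (one hemisphere).
DK_CORTICAL_34: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: 17 subcortical structures: brain stem plus 8 bilateral nuclei.
SUBCORTICAL_17: tuple[str, ...] = (
    "Brain-stem",
    "Left-cerebellum",
    "Right-cerebellum",
    "Left-thalamus",
    "Right-thalamus",
    "Left-caudate",
    "Right-caudate",
    "Left-putamen",
    "Right-putamen",
    "Left-pallidum",
    "Right-pallidum",
    "Left-hippocampus",
    "Right-hippocampus",
    "Left-amygdala",
    "Right-amygdala",
    "Left-accumbens",
    "Right-accumbens",
)


@dataclass(frozen=True)
class Region:
    """A single parcellation region.

    Attributes
    ----------
    label : str
        Unique region name, e.g. ``"lh-precentral"`` or ``"Left-caudate"``.
    hemisphere : str
        ``"left"``, ``"right"`` or ``"none"`` (midline structures).
    tissue : str
        ``"cortical"`` or ``"subcortical"``.
    """

    label: str
    hemisphere: str
    tissue: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "none"):
            raise ValidationError(f"bad hemisphere {self.hemisphere!r}")
        if self.tissue not in ("cortical", "subcortical"):
            raise ValidationError(f"bad tissue {self.tissue!r}")
        if self.hemisphere == "none" and self.tissue == "cortical":
            raise ValidationError(
                f"cortical region {self.label!r} must have a hemisphere"
            )


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of regions defining node identity for all matrices."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate region labels: {dupes}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.regions)

    @property
    def hemispheres(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.regions])

    @property
    def tissues(self) -> np.ndarray:
        return np.array([r.tissue for r in self.regions])

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.tissues == "cortical"

    def index_of(self, label: str) -> int:
        for i, r in enumerate(self.regions):
            if r.label == label:
                return i
        raise KeyError(label)


def _subcortical_hemisphere(label: str) -> str:
    if label.startswith("Left-"):
        return "left"
    if label.startswith("Right-"):
        return "right"
    return "none"


def generate_parcellation(
    n_cortical_per_hemi: int = 34,
    subcortical_labels: Sequence[str] = SUBCORTICAL_17,
    cortical_names: Sequence[str] | None = None,
) -> Parcellation:
    """Build a parcellation with ``lh-``/``rh-`` cortical pairs plus
    subcortical structures.

    Cortical labels are ``lh-<name>`` / ``rh-<name>``; subcortical
    hemisphere is inferred from a ``Left-``/``Right-`` label prefix and is
    ``none`` otherwise (midline structures such as the brain stem).

    With the defaults this reproduces the 85-region extended
    Desikan-Killiany scheme: 34 cortical regions per hemisphere plus 17
    subcortical regions.
    """
    if n_cortical_per_hemi < 1:
        raise ValidationError("n_cortical_per_hemi must be >= 1")
    if len(subcortical_labels) == 0:
        raise ValidationError("subcortical_labels must be nonempty")
    if len(set(subcortical_labels)) != len(subcortical_labels):
        raise ValidationError("subcortical labels must be unique")
    if cortical_names is None:
        if n_cortical_per_hemi <= len(DK_CORTICAL_34):
            cortical_names = DK_CORTICAL_34[:n_cortical_per_hemi]
        else:
            cortical_names = tuple(
                f"region{i:03d}" for i in range(n_cortical_per_hemi)
            )
    if len(cortical_names) != n_cortical_per_hemi:
        raise ValidationError("cortical_names length mismatch")

    regions: list[Region] = []
    for hemi, prefix in (("left", "lh-"), ("right", "rh-")):
        for name in cortical_names:
            regions.append(Region(prefix + name, hemi, "cortical"))
    for label in subcortical_labels:
        regions.append(
            Region(label, _subcortical_hemisphere(label), "subcortical")
        )
    return Parcellation(tuple(regions))


def default_parcellation() -> Parcellation:
    """The default 85-region parcellation (68 cortical + 17 subcortical)."""
    return generate_parcellation(34, SUBCORTICAL_17)


@dataclass(frozen=True)
class ExpressionProfile:
    """Normalized regional expression of one gene.

    ``values`` holds one number per parcellation region, in region order.
    Values are unitless; profiles produced by donor averaging are
    z-scored within donor before averaging, so they are approximately
    centred on zero.
    """

    gene: str
    labels: tuple[str, ...]
    values: np.ndarray
    donor_count: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.labels):
            raise ValidationError("one expression value per region required")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if self.donor_count < 1:
            raise ValidationError("donor_count must be >= 1")

    def aligned_to(self, parcellation: Parcellation) -> np.ndarray:
        """Values reindexed to ``parcellation`` region order."""
        if self.labels == parcellation.labels:
            return self.values
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [pos[lab] for lab in parcellation.labels]
        except KeyError as err:
            raise ValidationError(
                f"expression profile missing region {err.args[0]!r}"
            ) from None
        return self.values[idx]


#: Control-group mean FA per anatomical edge class.
DEFAULT_CLASS_MEAN_FA: Mapping[str, float] = {
    "subcortical": 0.18,
    "left": 0.33,
    "right": 0.30,
    "interhemispheric": 0.06,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic case/control cohort.

    Attributes
    ----------
    n_pairs : int
        Number of age-matched case/control pairs (default 7).
    density : float
        Expected fraction of nonzero edges in control networks.
    class_mean_fa : mapping
        Control mean FA per edge class (``subcortical``, ``left``,
        ``right``, ``interhemispheric``).
    global_attenuation : float
        Multiplicative case/control ratio applied to every case edge
        (counts and FA); 1.0 is a null cohort.
    expression_coupling : float
        Slope linking regional expression to additional case-side nodal
        attenuation: node ``i`` carries factor
        ``clip(1 - coupling * expr_i, floor, 1)`` on its incident edges.
    subject_noise_sd : float
        Per-edge between-subject FA noise scale.
    count_scale : float
        Mean streamline count of supra-threshold control edges.
    seed : int
        Root seed; expanded into per-subject substreams via
        ``numpy.random.SeedSequence(seed).spawn`` (one child per cohort
        structure draw, then one per subject, in manifest order).
    """

    n_pairs: int = 7
    density: float = 0.35
    class_mean_fa: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEAN_FA)
    )
    global_attenuation: float = 0.55
    expression_coupling: float = 0.15
    subject_noise_sd: float = 0.03
    count_scale: float = 12.0
    seed: int = 0
    nodal_factor_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if not 0.0 < self.density <= 1.0:
            raise ValidationError("density must be in (0, 1]")
        if not 0.0 < self.global_attenuation <= 1.0:
            raise ValidationError("global_attenuation must be in (0, 1]")
        for cls, mean in self.class_mean_fa.items():
            if not 0.0 < mean < 1.0:
                raise ValidationError(
                    f"class_mean_fa[{cls!r}] must be in (0, 1)"
                )
        if self.subject_noise_sd < 0:
            raise ValidationError("subject_noise_sd must be >= 0")
        if self.count_scale <= 0:
            raise ValidationError("count_scale must be > 0")


@dataclass(frozen=True)
class Subject:
    """One scanned individual: id, age and raw connectivity matrices."""

    subject_id: str
    age: float
    count_matrix: np.ndarray
    fa_matrix: np.ndarray


@dataclass(frozen=True)
class SubjectPair:
    case: Subject
    control: Subject


@dataclass(frozen=True)
class Cohort:
    """Age-matched case/control pairs sharing one parcellation."""

    pairs: tuple[SubjectPair, ...]
    parcellation: Parcellation

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def subjects(self) -> tuple[Subject, ...]:
        out: list[Subject] = []
        for p in self.pairs:
            out.extend((p.case, p.control))
        return tuple(out)

    def validate(self) -> None:
        n = self.parcellation.n_regions
        for subj in self.subjects:
            for name, m in (
                ("count", subj.count_matrix),
                ("fa", subj.fa_matrix),
            ):
                if m.shape != (n, n):
                    raise ValidationError(
                        f"{subj.subject_id} {name} matrix has shape "
                        f"{m.shape}, expected {(n, n)}"
                    )
                if not np.allclose(m, m.T):
                    raise ValidationError(
                        f"{subj.subject_id} {name} matrix not symmetric"
                    )
                if np.any(np.diag(m) != 0):
                    raise ValidationError(
                        f"{subj.subject_id} {name} matrix has nonzero diagonal"
                    )
                if np.any(m < 0):
                    raise ValidationError(
                        f"{subj.subject_id} {name} matrix has negative entries"
                    )
        for p in self.pairs:
            if abs(p.case.age - p.control.age) > 2.0 + 1e-9:
                raise ValidationError(
                    f"pair ({p.case.subject_id}, {p.control.subject_id}) "
                    "not age-matched within 2 years"
                )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a synthetic cohort, for recovery tests."""

    global_ratio: float
    coupled_nodes: frozenset[str]
    expression_slope: float
    is_null: bool


def generate_expression_map(
    parcellation: Parcellation,
    left_offset: float = 0.5,
    spatial_sd: float = 1.0,
    seed: int = 0,
    gene: str = "GENE",
) -> ExpressionProfile:
    """Draw a synthetic regional expression map with a hemispheric gradient.

    Every region's value is drawn ``Normal(mu, spatial_sd)`` with
    ``mu = left_offset`` for left cortical regions and 0 otherwise, so
    left-hemisphere cortex is on average ``left_offset`` higher than the
    right — the kind of lateralised expression gradient seen for genes
    with asymmetric cortical expression. With ``spatial_sd = 0`` the
    left/right difference is exact. Deterministic given ``seed``.
    """
    if spatial_sd < 0:
        raise ValidationError("spatial_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = np.where(
        (parcellation.hemispheres == "left") & parcellation.cortical_mask,
        float(left_offset),
        0.0,
    )
    values = mu + spatial_sd * rng.standard_normal(parcellation.n_regions)
    return ExpressionProfile(
        gene=gene, labels=parcellation.labels, values=values, donor_count=1
    )


def _support_mask(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random edge support: a spanning-tree backbone plus Bernoulli edges.

    The spanning tree guarantees connectedness (and a consensus backbone
    shared by every subject); additional unordered pairs are included
    independently so that the expected overall density equals ``density``.
    """
    total_pairs = n * (n - 1) // 2
    support = np.zeros((n, n), dtype=bool)
    order = rng.permutation(n)
    for k in range(1, n):
        child = order[k]
        parent = order[rng.integers(0, k)]
        support[child, parent] = support[parent, child] = True
    extra = density * total_pairs - (n - 1)
    p_extra = max(0.0, extra / (total_pairs - (n - 1)))
    iu = np.triu_indices(n, k=1)
    add = rng.random(total_pairs) < p_extra
    mask_flat = support[iu] | add
    support[iu] = mask_flat
    support.T[iu] = mask_flat
    return support


def _truncated_normal(
    means: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-edge FA draws truncated to (0, 1); degenerate at sd = 0."""
    if sd == 0:
        return np.clip(means, 1e-12, 1.0)
    a = (0.0 - means) / sd
    b = (1.0 - means) / sd
    return stats.truncnorm.rvs(a, b, loc=means, scale=sd, random_state=rng)


def _nodal_factors(
    expression: np.ndarray, coupling: float, floor: float
) -> np.ndarray:
    return np.clip(1.0 - coupling * expression, floor, 1.0)


def _subject_matrices(
    support: np.ndarray,
    class_means: np.ndarray,
    edge_factor: np.ndarray,
    spec: SyntheticSpec,
    attenuation: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = support.shape[0]
    iu = np.triu_indices(n, k=1)
    on = support[iu]
    fa = np.zeros((n, n))
    counts = np.zeros((n, n))
    fa_means = (class_means[iu][on] * attenuation * edge_factor[iu][on])
    fa_vals = _truncated_normal(fa_means, spec.subject_noise_sd, rng)
    count_means = np.maximum(
        spec.count_scale * attenuation * edge_factor[iu][on] - 1.0, 0.0
    )
    if spec.subject_noise_sd == 0:
        # noise-free cohorts are fully deterministic (counts included)
        count_vals = 1.0 + np.round(count_means)
    else:
        count_vals = 1.0 + rng.poisson(count_means)
    fa_flat = np.zeros(len(on))
    fa_flat[on] = fa_vals
    count_flat = np.zeros(len(on))
    count_flat[on] = count_vals
    fa[iu] = fa_flat
    fa.T[iu] = fa_flat
    counts[iu] = count_flat
    counts.T[iu] = count_flat
    return counts, fa


def generate_cohort(
    parcellation: Parcellation,
    expression: ExpressionProfile,
    spec: SyntheticSpec,
) -> Cohort:
    """Simulate an age-matched case/control cohort with planted effects.

    Control edge FA is drawn from a normal truncated to (0, 1) around the
    anatomical-class mean; streamline counts are shifted Poisson with mean
    ``count_scale``. Case edges are drawn around
    ``class_mean * global_attenuation * sqrt(g_i * g_j)`` where
    ``g_i = clip(1 - expression_coupling * expr_i, floor, 1)`` is the
    nodal attenuation factor, and case counts are scaled the same way, so
    the planted deficit shows up in edge weight, degree and strength
    alike. All subjects share one edge support (spanning tree + random
    pairs at the target density), so with zero noise and no planted
    effect, case and control matrices are identical within each pair.

    Reproducible: the root seed is expanded deterministically into one
    substream for the cohort structure (support, ages) and one per
    subject.
    """
    expr = expression.aligned_to(parcellation)  # raises on mismatch
    n = parcellation.n_regions
    n_streams = 1 + 2 * spec.n_pairs
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(spec.seed).spawn(n_streams)
    ]
    struct_rng, subject_rngs = streams[0], streams[1:]

    support = _support_mask(n, spec.density, struct_rng)
    from .connectome import edge_class_matrix  # local import, avoids cycle

    class_codes = edge_class_matrix(parcellation)
    class_means = np.zeros((n, n))
    for cls, mean in spec.class_mean_fa.items():
        class_means[class_codes == cls] = mean

    g = _nodal_factors(expr, spec.expression_coupling, spec.nodal_factor_floor)
    edge_factor = np.sqrt(np.outer(g, g))
    no_factor = np.ones((n, n))

    control_ages = struct_rng.uniform(10.0, 43.0, size=spec.n_pairs)
    age_jitter = struct_rng.uniform(-2.0, 2.0, size=spec.n_pairs)

    pairs: list[SubjectPair] = []
    for k in range(spec.n_pairs):
        case_rng, control_rng = subject_rngs[2 * k], subject_rngs[2 * k + 1]
        case_counts, case_fa = _subject_matrices(
            support, class_means, edge_factor, spec,
            spec.global_attenuation, case_rng,
        )
        ctrl_counts, ctrl_fa = _subject_matrices(
            support, class_means, no_factor, spec, 1.0, control_rng,
        )
        control_age = float(control_ages[k])
        case_age = float(np.clip(control_age + age_jitter[k], 8.0, 45.0))
        pairs.append(
            SubjectPair(
                case=Subject(f"case-{k:02d}", case_age, case_counts, case_fa),
                control=Subject(
                    f"control-{k:02d}", control_age, ctrl_counts, ctrl_fa
                ),
            )
        )
    return Cohort(pairs=tuple(pairs), parcellation=parcellation)


def planted_truth(
    spec: SyntheticSpec, expression: ExpressionProfile
) -> PlantedTruth:
    """Record of the effects planted by :func:`generate_cohort`.

    ``coupled_nodes`` is the set of region labels whose nodal attenuation
    factor is strictly below the median factor (empty when coupling is
    zero, i.e. all factors equal 1).
    """
    g = _nodal_factors(
        np.asarray(expression.values, dtype=float),
        spec.expression_coupling,
        spec.nodal_factor_floor,
    )
    if spec.expression_coupling == 0:
        coupled: frozenset[str] = frozenset()
    else:
        med = float(np.median(g))
        coupled = frozenset(
            lab for lab, gi in zip(expression.labels, g) if gi < med
        )
    return PlantedTruth(
        global_ratio=spec.global_attenuation,
        coupled_nodes=coupled,
        expression_slope=spec.expression_coupling,
        is_null=(
            spec.global_attenuation == 1.0 and spec.expression_coupling == 0.0
        ),
    )
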