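"""Synthetic two-site cohort generator.

Emulates the data structure of a multi-site case-control morphometry study
of youth born with complex congenital heart disease (CHD): vertex-wise
cortical thickness (CT, mm), cortical surface area (SA, mm²) and local
gyrification index (GI, dimensionless) for every subject, plus a cohort
table carrying demographics, site, executive-function T-scores modelled on
the BRIEF-A (9 subscales, 2 indices, 1 global composite; population mean 50,
SD 10, T >= 65 clinically abnormal) and CHD-only clinical variables.

The generative model is additive and parts-based, matching the structure a
non-negative factorization assumes::

    X_metric = W_true @ H_metric + site batch effects + Gaussian noise

where ``W_true`` holds k spatially contiguous, pairwise disjoint component
maps and ``H_metric`` holds non-negative subject weights driven by shared
latent scores ``u`` (k x n).  The same latent scores, together with group
status, drive the behaviour scales, so brain-behaviour coupling is planted
with known ground truth and downstream recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import Geometry, grid_geometry

#: the 12 executive-function scales: 9 subscales, 2 indices, global composite
BRIEF_SCALES = [
    "brief_inhibit",
    "brief_shift",
    "brief_emotional_control",
    "brief_self_monitor",
    "brief_initiate",
    "brief_working_memory",
    "brief_plan_organize",
    "brief_task_monitor",
    "brief_organization_materials",
    "brief_bri",
    "brief_mi",
    "brief_gec",
]

METRICS = ("ct", "sa", "gi")

CLINICAL_COLUMNS = ("age_first_surgery", "cross_clamp_time")


@dataclass
class VertexFeatureSet:
    """Three vertex x subject matrices sharing one geometry and subject order."""

    ct: np.ndarray
    sa: np.ndarray
    gi: np.ndarray
    geometry: Geometry
    subject_order: list

    def __post_init__(self):
        shapes = {m: getattr(self, m).shape for m in METRICS}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"metric matrices disagree in shape: {shapes}")
        if self.ct.shape[1] != len(self.subject_order):
            raise ValueError(
                f"{self.ct.shape[1]} feature columns vs "
                f"{len(self.subject_order)} subjects"
            )

    @property
    def metrics(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_order)

    def validate(self):
        """Check value invariants on analysable (unmasked) vertices."""
        un = self.geometry.unmasked
        for m, x in self.metrics.items():
            if not np.isfinite(x).all():
                raise ValueError(f"{m}: non-finite values")
        if (self.ct[un] <= 0).any():
            raise ValueError("ct: non-positive thickness at unmasked vertices")
        if (self.sa[un] < 0).any() or (self.gi[un] < 0).any():
            raise ValueError("sa/gi must be non-negative at unmasked vertices")


@dataclass
class GroundTruth:
    """Planted structure a simulation run was built from."""

    W_true: np.ndarray  # vertices x k, disjoint support, >= 0
    H_true: dict  # metric -> k x n_subjects, >= 0
    labels: np.ndarray  # per-vertex component id, -1 = none
    latent_scores: np.ndarray  # u, k x n_subjects
    coupling: np.ndarray  # n_scales x k
    batch_effects: dict
    noise_sd: dict

    @property
    def k(self) -> int:
        return self.W_true.shape[1]

    def H_stacked(self, metric_order=METRICS) -> np.ndarray:
        """k x (subjects * metrics) weight matrix, metric-major blocks."""
        return np.hstack([self.H_true[m] for m in metric_order])


def _default_coupling(k: int) -> np.ndarray:
    """Brain-behaviour coupling: one dominant latent pattern.

    Component 0 drives the working-memory-flavoured scales and the summary
    indices; component 1 (if present) weakly drives the regulation scales
    with opposite sign.  Rows are indexed by :data:`BRIEF_SCALES`.
    """
    C = np.zeros((len(BRIEF_SCALES), k))
    primary = [
        BRIEF_SCALES.index(s)
        for s in (
            "brief_inhibit",
            "brief_working_memory",
            "brief_plan_organize",
            "brief_mi",
            "brief_gec",
        )
    ]
    C[primary, 0] = 0.30
    if k >= 2:
        secondary = [
            BRIEF_SCALES.index(s)
            for s in ("brief_shift", "brief_emotional_control", "brief_bri")
        ]
        C[secondary, 1] = -0.20
    return C


def _default_behavior_group_effect() -> np.ndarray:
    """Group effect (in SD units) per scale: cases worse on most scales."""
    eff = np.full(len(BRIEF_SCALES), 0.25)
    worse = (
        "brief_inhibit",
        "brief_working_memory",
        "brief_plan_organize",
        "brief_task_monitor",
        "brief_initiate",
        "brief_emotional_control",
        "brief_mi",
        "brief_gec",
    )
    for s in worse:
        eff[BRIEF_SCALES.index(s)] = 0.55
    return eff


def _default_brain_group_effect(k: int) -> np.ndarray:
    eff = np.zeros(k)
    base = [0.6, -0.45, 0.35]
    eff[: min(k, 3)] = base[: min(k, 3)]
    return eff


@dataclass
class SimulationSpec:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions every stage is exercised under:
    two balanced sites, 60 subjects per group, a 2,000-vertex two-hemisphere
    grid, k = 6 planted components tiling the unmasked surface, subject
    weights with ~20% coefficient of variation, additive/multiplicative/
    rank-1 site effects, and behaviour scales with unit total variance on
    the T-score scale.
    """

    n_per_group: int = 60
    grid_shape: tuple = (25, 40)  # per-hemisphere rows x cols -> 2000 vertices
    k: int = 6
    patch_size: int = None  # None -> components tile the unmasked surface
    metric_scales: dict = field(
        default_factory=lambda: {"ct": 3.0, "sa": 12.0, "gi": 2.5}
    )
    h_sd: float = 0.2
    noise_sd: dict = field(
        default_factory=lambda: {"ct": 0.12, "sa": 0.5, "gi": 0.1}
    )
    # site ("batch") effects, applied to the second site only
    batch_shift: dict = field(
        default_factory=lambda: {"ct": 0.15, "sa": 0.8, "gi": 0.12}
    )
    batch_var_scale: dict = field(
        default_factory=lambda: {"ct": 1.3, "sa": 1.3, "gi": 1.3}
    )
    batch_cov_strength: dict = field(
        default_factory=lambda: {"ct": 0.10, "sa": 0.4, "gi": 0.08}
    )
    # latent-score structure
    brain_group_effect: np.ndarray = None  # per component, SD units
    brain_age_effect: float = 0.15  # on component 0, per SD of age
    brain_sex_effect: float = 0.10  # on component 0
    vol_coef: float = 0.15  # volume modulation of subject weights
    # behaviour block
    coupling: np.ndarray = None  # n_scales x k
    behavior_group_effect: np.ndarray = None  # per scale, SD units
    # demographics / clinical
    age_range: tuple = (16.0, 32.0)
    volume_mean: float = 5.5e5
    volume_sd: float = 4.0e4
    volume_group_effect: float = -2.5e4
    lesion_rate: tuple = (0.05, 0.30)  # control, case
    maternal_education_rate: float = 0.6
    missing_fraction: float = 0.12  # MCAR on CHD-only clinical variables

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for d in (self.noise_sd, self.batch_shift):
            for m, v in d.items():
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"negative or non-finite parameter for {m}")
        if self.brain_group_effect is None:
            self.brain_group_effect = _default_brain_group_effect(self.k)
        self.brain_group_effect = np.asarray(self.brain_group_effect, float)
        if self.coupling is None:
            self.coupling = _default_coupling(self.k)
        self.coupling = np.asarray(self.coupling, float)
        if self.coupling.shape != (len(BRIEF_SCALES), self.k):
            raise ValueError(
                f"coupling must be {len(BRIEF_SCALES)} x {self.k}, "
                f"got {self.coupling.shape}"
            )
        if self.behavior_group_effect is None:
            self.behavior_group_effect = _default_behavior_group_effect()
        self.behavior_group_effect = np.asarray(self.behavior_group_effect, float)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("brain_group_effect", "coupling", "behavior_group_effect"):
            d[key] = np.asarray(d[key]).tolist()
        d["grid_shape"] = list(self.grid_shape)
        d["age_range"] = list(self.age_range)
        d["lesion_rate"] = list(self.lesion_rate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        for key in ("grid_shape", "age_range", "lesion_rate"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("brain_group_effect", "coupling", "behavior_group_effect"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], float)
        return cls(**d)


def simulate_components(
    geometry: Geometry,
    k: int,
    patch_size: int = None,
    seed: int = 0,
    rng: np.random.Generator = None,
):
    """Plant k contiguous, pairwise disjoint non-negative component maps.

    Patches are grown by round-robin breadth-first region growing from
    random seed vertices on the unmasked surface.  With ``patch_size=None``
    the patches tile the whole unmasked surface (a full parcellation, the
    regime a parts-based factorization produces on real cortex); otherwise
    each patch is grown to exactly ``patch_size`` vertices.

    Returns ``(W_true, labels)`` where ``W_true`` is vertices x k with
    disjoint column support (loadings uniform on [0.5, 1.5]) and ``labels``
    assigns each vertex its component (-1 = unassigned or masked).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    unmasked = geometry.unmasked
    fill = patch_size is None
    if not fill and k * patch_size > unmasked.size:
        raise ValueError(
            f"k * patch_size = {k * patch_size} exceeds "
            f"{unmasked.size} unmasked vertices"
        )
    if fill and k < 2:
        raise ValueError("tiling both hemispheres requires k >= 2")

    labels = np.full(geometry.n_vertices, -1, dtype=int)

    # seeds: in fill mode, split across hemispheres so every unmasked vertex
    # is reachable from some patch
    if fill:
        left = unmasked[geometry.hemisphere[unmasked] == "L"]
        right = unmasked[geometry.hemisphere[unmasked] == "R"]
        k_left = max(1, min(k - 1, round(k * left.size / unmasked.size)))
        seeds = np.concatenate(
            [
                rng.choice(left, size=k_left, replace=False),
                rng.choice(right, size=k - k_left, replace=False),
            ]
        )
    else:
        seeds = rng.choice(unmasked, size=k, replace=False)

    allowed = np.zeros(geometry.n_vertices, dtype=bool)
    allowed[unmasked] = True
    frontiers = []
    sizes = np.zeros(k, dtype=int)
    for c, s in enumerate(seeds):
        labels[s] = c
        sizes[c] = 1
        frontiers.append([s])

    target = unmasked.size if fill else k * patch_size
    claimed = k
    active = set(range(k))
    while claimed < target and active:
        for c in sorted(active):
            if not fill and sizes[c] >= patch_size:
                active.discard(c)
                continue
            grown = False
            while frontiers[c]:
                v = frontiers[c].pop(0)
                nbrs = geometry.neighbors(v)
                free = [u for u in nbrs if allowed[u] and labels[u] == -1]
                if not free:
                    continue
                u = free[int(rng.integers(len(free)))]
                labels[u] = c
                sizes[c] += 1
                claimed += 1
                # keep v in play if it may still have free neighbours
                frontiers[c].insert(0, v)
                frontiers[c].append(u)
                grown = True
                break
            if not grown:
                active.discard(c)
    if not fill and (sizes < patch_size).any():
        raise ValueError(
            "region growing stalled before reaching patch_size; "
            "reduce k or patch_size"
        )
    if fill and claimed < target:
        # absorb stranded vertices into an adjacent patch
        remaining = [v for v in unmasked if labels[v] == -1]
        while remaining:
            progressed = False
            still = []
            for v in remaining:
                lab = labels[geometry.neighbors(v)]
                lab = lab[lab >= 0]
                if lab.size:
                    labels[v] = lab[0]
                    progressed = True
                else:
                    still.append(v)
            if not progressed:
                raise ValueError("unmasked surface not reachable from seeds")
            remaining = still

    W = np.zeros((geometry.n_vertices, k))
    for c in range(k):
        members = np.flatnonzero(labels == c)
        W[members, c] = rng.uniform(0.5, 1.5, size=members.size)
    return W, labels


def _subject_ids(n: int) -> list:
    return [f"S{i:04d}" for i in range(n)]


def simulate_cohort(spec: SimulationSpec = None, seed: int = 0):
    """Generate a full synthetic cohort.

    Returns ``(cohort, features, truth)``: a cohort table (one row per
    subject), the vertex-wise feature set, and the planted ground truth.
    Bit-identical output for a fixed ``(spec, seed)``.
    """
    spec = SimulationSpec() if spec is None else spec
    rng = np.random.default_rng(seed)
    geom = grid_geometry(*spec.grid_shape)
    W, labels = simulate_components(geom, spec.k, spec.patch_size, rng=rng)

    n = 2 * spec.n_per_group
    ids = _subject_ids(n)
    group = np.repeat([1, 0], spec.n_per_group)
    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.random(n) < 0.5).astype(int)
    # balanced site assignment within each group (two batches, both mixed)
    site = np.empty(n, dtype=object)
    for g in (0, 1):
        idx = rng.permutation(np.flatnonzero(group == g))
        site[idx[: idx.size // 2]] = "site1"
        site[idx[idx.size // 2 :]] = "site2"
    site_ind = (site == "site2").astype(int)

    maternal_education = (rng.random(n) < spec.maternal_education_rate).astype(int)
    lesion = (
        rng.random(n) < np.where(group == 1, spec.lesion_rate[1], spec.lesion_rate[0])
    ).astype(int)

    volume = (
        spec.volume_mean
        + spec.volume_group_effect * group
        + rng.normal(0, spec.volume_sd, size=n)
    )
    volume = np.clip(volume, 1e4, None)
    volz = (volume - volume.mean()) / volume.std()

    # latent component scores shared by brain weights and behaviour
    g_c = group - 0.5
    age_z = (age - age.mean()) / age.std()
    u = rng.standard_normal((spec.k, n))
    u += np.outer(spec.brain_group_effect[: spec.k], g_c)
    u[0] += spec.brain_age_effect * age_z + spec.brain_sex_effect * (sex - 0.5)

    H = {}
    for m in METRICS:
        raw = 1.0 + spec.h_sd * u + spec.vol_coef * volz[None, :]
        H[m] = spec.metric_scales[m] * np.clip(raw, 0.05, None)

    feats = {}
    for m in METRICS:
        X = W @ H[m]
        if spec.noise_sd[m] > 0:
            X = X + rng.normal(0.0, spec.noise_sd[m], size=X.shape)
        # second-site batch effects: location + scale + rank-1 covariance
        s2 = np.flatnonzero(site_ind == 1)
        if s2.size and (
            spec.batch_shift[m] != 0
            or spec.batch_var_scale[m] != 1
            or spec.batch_cov_strength[m] != 0
        ):
            mu2 = X[:, s2].mean(axis=1, keepdims=True)
            X[:, s2] = mu2 + np.sqrt(spec.batch_var_scale[m]) * (X[:, s2] - mu2)
            X[:, s2] += spec.batch_shift[m]
            if spec.batch_cov_strength[m] != 0:
                a = rng.standard_normal(X.shape[0])
                v = rng.standard_normal(s2.size)
                X[:, s2] += spec.batch_cov_strength[m] * np.outer(a, v)
        if spec.noise_sd[m] > 0 or spec.batch_shift[m] != 0:
            # physical floors: thickness stays positive, area/folding
            # non-negative (touched only in the extreme noise tail)
            X = np.maximum(X, 0.01 if m == "ct" else 0.0)
        feats[m] = X

    features = VertexFeatureSet(
        ct=feats["ct"], sa=feats["sa"], gi=feats["gi"],
        geometry=geom, subject_order=list(ids),
    )

    # behaviour block: T-scores with unit total variance per scale
    C = spec.coupling
    struct = C @ u + spec.behavior_group_effect[:, None] * g_c[None, :]
    struct_var = (C**2).sum(axis=1) + spec.behavior_group_effect**2 / 4.0
    noise_scale = np.sqrt(np.clip(1.0 - struct_var, 0.15, None))
    brief = 50.0 + 10.0 * (
        struct + noise_scale[:, None] * rng.standard_normal(struct.shape)
    )

    cohort = pd.DataFrame(
        {
            "subject_id": ids,
            "site": site,
            "group": group,
            "age": age,
            "sex": sex,
            "maternal_education": maternal_education,
            "lesion": lesion,
            "total_cgm_volume": volume,
        }
    )
    for i, s in enumerate(BRIEF_SCALES):
        cohort[s] = brief[i]

    # CHD-only clinical variables with MCAR missingness
    afs = np.where(group == 1, rng.gamma(shape=1.2, scale=5.0, size=n), np.nan)
    cct = np.where(
        group == 1, np.clip(rng.normal(72.7, 31.4, size=n), 5.0, None), np.nan
    )
    for name, vals in (("age_first_surgery", afs), ("cross_clamp_time", cct)):
        v = vals.copy()
        chd = np.flatnonzero(group == 1)
        drop = chd[rng.random(chd.size) < spec.missing_fraction]
        v[drop] = np.nan
        cohort[name] = v

    truth = GroundTruth(
        W_true=W,
        H_true=H,
        labels=labels,
        latent_scores=u,
        coupling=C,
        batch_effects={
            "shift": dict(spec.batch_shift),
            "var_scale": dict(spec.batch_var_scale),
            "cov_strength": dict(spec.batch_cov_strength),
        },
        noise_sd=dict(spec.noise_sd),
    )
    return cohort, features, truth
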