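"""Seeded synthetic-data generators for the analysis pipeline.

Generates the three kinds of input the downstream analyses consume,
each with ground truth for parameter-recovery tests:

* super-resolution-like images of fluorescent protein clusters on the
  surface of a mitochondrial tubule (a cylinder, orthographically
  projected to the image plane), under four spatial models — randomly
  scattered puncta, perpendicular stripe patterns, two opposite
  longitudinal distribution bands, and extended ring/rib arcs;
* MINFLUX localization-event tables mixing valid single-molecule
  events with artifact events that each violate a known QC criterion;
* per-section EM morphometry tables with condition presets for CJ
  frequency, CJ diameter, and septum prevalence.

Random-number contract: every generator derives its stream from
``numpy.random.SeedSequence([seed, STREAM_ID])`` with a fixed stream id
per generator (scene placement 0, rendering noise 1, MINFLUX events 2,
morphometry 3), so outputs are bit-reproducible and independent across
pipeline stages sharing one root seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .cluster_metric import SIGMA_PER_FWHM, Image2D
from .minflux_filter import REASONS, MinfluxEvent
from .morphometry import SectionMorphometry

__all__ = [
    "SceneModel",
    "SceneParams",
    "SceneGroundTruth",
    "MorphometryPreset",
    "MinfluxSimulation",
    "simulate_scene",
    "render_image",
    "simulate_minflux_events",
    "simulate_morphometry",
    "PRESET_WT",
    "PRESET_MIC10_KO",
    "PRESET_MIC60_KO",
    "PRESET_MIC10_KO_CTRL",
    "PRESET_MIC10_KO_OPA1_KD",
]

_STREAM_SCENE = 0
_STREAM_RENDER = 1
_STREAM_MINFLUX = 2
_STREAM_MORPHOMETRY = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, stream])))


class SceneModel(enum.Enum):
    """Spatial model of cluster placement on the tubule surface."""

    SCATTERED_PUNCTA = "scattered_puncta"
    STRIPE_PATTERN = "stripe_pattern"
    OPPOSITE_BANDS = "opposite_bands"
    EXTENDED_ASSEMBLIES = "extended_assemblies"


@dataclass(frozen=True)
class SceneParams:
    """Geometry, labeling and imaging parameters of a synthetic scene.

    Lengths are nanometres unless suffixed otherwise.  The defaults
    describe a 2 um mitochondrial tubule of 150 nm radius imaged at
    20 nm pixels with a 60 nm FWHM effective PSF — typical 2D STED
    conditions for immunolabeled MICOS subunits.
    """

    model: SceneModel = SceneModel.SCATTERED_PUNCTA
    tubule_length_um: float = 2.0
    tubule_radius_nm: float = 150.0
    n_clusters: int = 30
    assembly_arc_deg: float = 120.0
    band_halfwidth_nm: float = 50.0
    stripe_period_nm: float = 150.0
    psf_fwhm_nm: float = 60.0
    pixel_size_nm: float = 20.0
    photons_per_emitter: float = 500.0
    background_rate: float = 2.0
    seed: int = 0
    # secondary knobs with sensible fixed defaults
    emitters_per_cluster: int = 8
    cluster_sigma_nm: float = 15.0
    assembly_emitter_spacing_nm: float = 10.0
    margin_nm: float = 200.0

    def __post_init__(self) -> None:
        if isinstance(self.model, str):  # accept enum values from config files
            object.__setattr__(self, "model", SceneModel(self.model))
        if not (self.tubule_length_um > 0 and self.tubule_radius_nm > 0):
            raise ValueError("tubule dimensions must be > 0")
        if not (5.0 <= self.pixel_size_nm <= 50.0):
            raise ValueError("pixel_size_nm must lie in [5, 50]")
        if self.psf_fwhm_nm < self.pixel_size_nm:
            raise ValueError("psf_fwhm_nm must be >= pixel_size_nm")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.photons_per_emitter <= 0:
            raise ValueError("photons_per_emitter must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.emitters_per_cluster < 1 or self.cluster_sigma_nm <= 0:
            raise ValueError("invalid cluster shape parameters")
        if self.margin_nm < 0 or self.assembly_emitter_spacing_nm <= 0:
            raise ValueError("invalid margin or emitter spacing")

    @property
    def tubule_length_nm(self) -> float:
        return self.tubule_length_um * 1000.0

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered image covering tubule + margin."""
        ny = math.ceil((2 * self.tubule_radius_nm + 2 * self.margin_nm) / self.pixel_size_nm)
        nx = math.ceil((self.tubule_length_nm + 2 * self.margin_nm) / self.pixel_size_nm)
        return (max(ny, 8), max(nx, 8))


@dataclass(frozen=True)
class SceneGroundTruth:
    """Emitter positions (after projection) with cluster labels.

    ``emitter_positions`` is an (N, 2) array of (x_nm, y_nm) in image
    coordinates (origin top-left, x along the tubule axis);
    ``cluster_membership`` assigns each emitter to its cluster id;
    ``cluster_centers`` are the projected cluster/arc centres.
    """

    emitter_positions: np.ndarray
    cluster_membership: np.ndarray
    cluster_centers: np.ndarray
    params: SceneParams


@dataclass(frozen=True)
class MorphometryPreset:
    """Condition preset for the morphometry simulator.

    ``cj_per_um`` is the crista-junction intensity per micrometre of
    outer membrane; ``p_section_has_junction``, when set, pins the
    fraction of sections bearing at least one junction of any kind
    (a hurdle model is then used, see simulate_morphometry);
    ``p_septum_given_junction`` is the fraction of junction-bearing
    sections whose junctions are septum-associated.
    """

    condition_label: str
    cj_per_um: float
    diameter_mean_nm: float
    diameter_sd_nm: float
    p_section_has_junction: float | None = None
    p_septum_given_junction: float = 0.0

    def __post_init__(self) -> None:
        if self.cj_per_um < 0:
            raise ValueError("cj_per_um must be >= 0")
        if self.diameter_sd_nm < 0:
            raise ValueError("diameter_sd_nm must be >= 0")
        if self.diameter_mean_nm <= 0:
            raise ValueError("diameter_mean_nm must be > 0")
        for p in (self.p_section_has_junction, self.p_septum_given_junction):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


# Condition presets.  CJ diameters follow the reported condition averages
# (~20 nm in wild type, ~28 nm without Mic10, ~32 nm for the rare
# connections without Mic60); diameter SDs and absolute CJ rates are not
# reported per section and are free parameters chosen to be realistic
# (wild-type rate 1 CJ/um, Mic10-KO ~20% of it, Mic60-KO close to zero).
PRESET_WT = MorphometryPreset("WT", cj_per_um=1.0, diameter_mean_nm=20.0, diameter_sd_nm=4.0)
PRESET_MIC10_KO = MorphometryPreset("Mic10-KO", cj_per_um=0.2, diameter_mean_nm=28.0, diameter_sd_nm=6.0)
PRESET_MIC60_KO = MorphometryPreset("Mic60-KO", cj_per_um=0.02, diameter_mean_nm=32.0, diameter_sd_nm=7.0)
# Junction/septum accounting presets: in Mic10-KO cells ~60% of sections
# bear a junction, ~15% of those septum-associated; with OPA1 additionally
# depleted, 36% and ~50%.
PRESET_MIC10_KO_CTRL = MorphometryPreset(
    "Mic10-KO+Ctrl", cj_per_um=0.2, diameter_mean_nm=28.0, diameter_sd_nm=6.0,
    p_section_has_junction=0.60, p_septum_given_junction=0.15,
)
PRESET_MIC10_KO_OPA1_KD = MorphometryPreset(
    "Mic10-KO+OPA1-KD", cj_per_um=0.2, diameter_mean_nm=28.0, diameter_sd_nm=6.0,
    p_section_has_junction=0.36, p_septum_given_junction=0.50,
)


# ---------------------------------------------------------------------------
# Scene simulation


def _cluster_centers(params: SceneParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cylinder-surface cluster centres as (axial_nm, theta_rad) arrays."""
    n = params.n_clusters
    length = params.tubule_length_nm
    r = params.tubule_radius_nm
    z = rng.uniform(0.0, length, size=n)
    if params.model is SceneModel.STRIPE_PATTERN:
        if params.stripe_period_nm <= 0:
            raise ValueError("stripe_period_nm must be > 0 for STRIPE_PATTERN")
        n_rings = max(1, int(length // params.stripe_period_nm))
        ring_z = (np.arange(n_rings) + 0.5) * params.stripe_period_nm
        ring_z = ring_z[ring_z <= length] if len(ring_z) else np.array([length / 2])
        z = rng.choice(ring_z, size=n)
        theta = rng.uniform(0.0, 2 * math.pi, size=n)
    elif params.model is SceneModel.OPPOSITE_BANDS:
        if params.band_halfwidth_nm <= 0:
            raise ValueError("band_halfwidth_nm must be > 0 for OPPOSITE_BANDS")
        # two diametrically opposed longitudinal strips at the projected
        # tubule edges: transverse offset magnitude in [r - halfwidth, r]
        side = rng.choice([-1.0, 1.0], size=n)
        offset = rng.uniform(max(0.0, r - params.band_halfwidth_nm), r, size=n)
        theta = np.arcsin(np.clip(side * offset / r, -1.0, 1.0))
    else:
        theta = rng.uniform(0.0, 2 * math.pi, size=n)
    return z, theta


def simulate_scene(params: SceneParams) -> SceneGroundTruth:
    """Place emitters on the tubule surface and project them to 2D.

    Cluster centres follow the chosen spatial model; member emitters
    jitter around their centre on the cylinder surface (Gaussian in
    axial and arc-length coordinates), except for extended assemblies,
    whose emitters run contiguously along an arc of
    ``assembly_arc_deg`` spanning the circumference.  The cylinder is
    orthographically projected onto the image plane (x axial,
    y = r sin(theta) transverse); axial positions are clamped to the
    tubule footprint.  Deterministic for fixed (params, seed).
    """
    if params.model is SceneModel.EXTENDED_ASSEMBLIES and params.assembly_arc_deg <= 0:
        raise ValueError("assembly_arc_deg must be > 0 for EXTENDED_ASSEMBLIES")
    rng = _rng(params.seed, _STREAM_SCENE)
    r = params.tubule_radius_nm
    length = params.tubule_length_nm
    z_c, theta_c = _cluster_centers(params, rng)

    zs, thetas, members = [], [], []
    for k in range(params.n_clusters):
        if params.model is SceneModel.EXTENDED_ASSEMBLIES:
            arc_rad = math.radians(params.assembly_arc_deg)
            arc_len = r * arc_rad
            n_e = max(2, int(round(arc_len / params.assembly_emitter_spacing_nm)))
            along = np.linspace(-arc_rad / 2, arc_rad / 2, n_e)
            theta = theta_c[k] + along
            z = z_c[k] + rng.normal(0.0, params.cluster_sigma_nm, size=n_e)
        else:
            n_e = params.emitters_per_cluster
            z = z_c[k] + rng.normal(0.0, params.cluster_sigma_nm, size=n_e)
            theta = theta_c[k] + rng.normal(0.0, params.cluster_sigma_nm / r, size=n_e)
        zs.append(np.clip(z, 0.0, length))
        thetas.append(theta)
        members.append(np.full(n_e, k, dtype=np.int32))

    if zs:
        z = np.concatenate(zs)
        theta = np.concatenate(thetas)
        membership = np.concatenate(members)
    else:
        z = np.empty(0)
        theta = np.empty(0)
        membership = np.empty(0, dtype=np.int32)

    m = params.margin_nm
    positions = np.column_stack([m + z, m + r + r * np.sin(theta)])
    centers = np.column_stack([m + z_c, m + r + r * np.sin(theta_c)])
    return SceneGroundTruth(positions, membership, centers, params)


def render_image(truth: SceneGroundTruth, noise: bool = True) -> Image2D:
    """Render a ground-truth scene into a pixel image.

    Each emitter contributes an isotropic Gaussian of the PSF FWHM
    whose discrete sum equals ``photons_per_emitter`` (up to PSF
    truncation at 5 sigma); a uniform background is added; with
    ``noise=True`` per-pixel Poisson noise is applied from the render
    stream of the scene's seed.
    """
    p = truth.params
    ny, nx = p.image_shape
    px = p.pixel_size_nm
    sigma_px = p.psf_fwhm_nm * SIGMA_PER_FWHM / px
    amp = p.photons_per_emitter / (2.0 * math.pi * sigma_px**2)
    half = int(math.ceil(5.0 * sigma_px))
    image = np.zeros((ny, nx), dtype=float)
    for x_nm, y_nm in truth.emitter_positions:
        # pixel centres sit at (i + 0.5) * pixel size
        col = x_nm / px - 0.5
        row = y_nm / px - 0.5
        c0, r0 = int(round(col)), int(round(row))
        cols = np.arange(max(0, c0 - half), min(nx, c0 + half + 1))
        rows = np.arange(max(0, r0 - half), min(ny, r0 + half + 1))
        if len(cols) == 0 or len(rows) == 0:
            continue
        gx = np.exp(-((cols - col) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((rows - row) ** 2) / (2 * sigma_px**2))
        image[np.ix_(rows, cols)] += amp * np.outer(gy, gx)
    image += p.background_rate
    if noise:
        rng = _rng(p.seed, _STREAM_RENDER)
        image = rng.poisson(image).astype(float)
    return Image2D(image, px)


# ---------------------------------------------------------------------------
# MINFLUX event simulation


@dataclass(frozen=True)
class MinfluxSimulation:
    """Simulated event mixture with per-event ground truth.

    ``failure_modes[i]`` is None for valid events, else the reason
    code of the criterion the artifact event was built to violate.
    """

    events: list[MinfluxEvent]
    is_valid: np.ndarray
    failure_modes: tuple[str | None, ...]


def _draw_valid(rng: np.random.Generator) -> dict[str, float]:
    return {
        "p0": rng.uniform(0.01, 0.10),
        "r_relative_nm": rng.uniform(2.0, 30.0),
        "count_rate_khz": rng.uniform(20.0, 100.0),
        "photons": float(rng.integers(1100, 5000)),
        "sbr": rng.uniform(0.7, 3.0),
    }


_ARTIFACT_DRAWS = {
    "P0": ("p0", lambda rng: rng.uniform(0.12, 0.30)),
    "R_RELATIVE": ("r_relative_nm", lambda rng: rng.uniform(33.0, 80.0)),
    "RATE": ("count_rate_khz", lambda rng: rng.uniform(101.0, 300.0)),
    "PHOTONS": ("photons", lambda rng: float(rng.integers(100, 1000))),
    "SBR": ("sbr", lambda rng: rng.uniform(0.05, 0.55)),
}


def simulate_minflux_events(
    n_valid: int, n_artifact: int, seed: int = 0
) -> MinfluxSimulation:
    """Simulate a shuffled mixture of valid and artifact events.

    Valid events are drawn so that all five QC criteria pass with the
    default thresholds; artifact events cycle round-robin through the
    five criteria, each violating exactly its assigned one (so every
    filter branch is covered).  Ordering is shuffled deterministically
    by the seed.
    """
    if n_valid < 0 or n_artifact < 0:
        raise ValueError("event counts must be >= 0")
    rng = _rng(seed, _STREAM_MINFLUX)
    events: list[MinfluxEvent] = []
    valid_flags: list[bool] = []
    modes: list[str | None] = []
    for _ in range(n_valid):
        fields = _draw_valid(rng)
        events.append(_make_event(rng, fields))
        valid_flags.append(True)
        modes.append(None)
    for j in range(n_artifact):
        code = REASONS[j % len(REASONS)]
        fields = _draw_valid(rng)
        name, draw = _ARTIFACT_DRAWS[code]
        fields[name] = draw(rng)
        events.append(_make_event(rng, fields))
        valid_flags.append(False)
        modes.append(code)
    order = rng.permutation(len(events))
    return MinfluxSimulation(
        events=[events[i] for i in order],
        is_valid=np.asarray(valid_flags, dtype=bool)[order],
        failure_modes=tuple(modes[i] for i in order),
    )


def _make_event(rng: np.random.Generator, fields: dict[str, float]) -> MinfluxEvent:
    return MinfluxEvent(
        x_nm=rng.uniform(0.0, 300.0),
        y_nm=rng.uniform(0.0, 300.0),
        z_nm=rng.uniform(-150.0, 150.0),
        **fields,
    )


# ---------------------------------------------------------------------------
# Morphometry simulation


def _zero_truncated_poisson(
    rng: np.random.Generator, lam: np.ndarray
) -> np.ndarray:
    """Vectorized zero-truncated Poisson via rejection."""
    out = rng.poisson(lam)
    bad = out == 0
    while np.any(bad):
        out[bad] = rng.poisson(lam[bad])
        bad = out == 0
    return out


def simulate_morphometry(
    preset: MorphometryPreset,
    n_sections: int,
    seed: int = 0,
    om_length_median_um: float = 3.0,
    om_length_sigma: float = 0.4,
) -> list[SectionMorphometry]:
    """Simulate per-section EM morphometry annotations for one condition.

    Outer-membrane lengths are log-normal with the given median and
    log-sd.  With ``p_section_has_junction`` unset, CJ counts are
    Poisson(cj_per_um x OM length) — the mode used for rate-recovery
    checks.  With it set, a hurdle model is used: CJ presence and an
    independent septum flag are Bernoulli with probabilities solved in
    closed form so that the fraction of junction-bearing sections and
    the septum-associated share among them match the preset in
    expectation, and positive counts are zero-truncated Poisson.
    CJ diameters are Normal(mean, sd) truncated at 0 by resampling.
    """
    if n_sections <= 0:
        raise ValueError("n_sections must be > 0")
    rng = _rng(seed, _STREAM_MORPHOMETRY)
    mu = math.log(om_length_median_um)
    lengths = rng.lognormal(mean=mu, sigma=om_length_sigma, size=n_sections)
    lam = preset.cj_per_um * lengths

    p_sep = preset.p_septum_given_junction
    if preset.p_section_has_junction is None:
        n_cj = rng.poisson(lam)
        # per-section septum probability targeting the conditional share
        q_i = -np.expm1(-lam)  # P(n_cj >= 1)
        denom = np.maximum(1.0 - p_sep * (1.0 - q_i), 1e-300)
        s_i = p_sep * q_i / denom
        septum = rng.random(n_sections) < s_i
    else:
        p_any = preset.p_section_has_junction
        if p_sep >= 1.0 and p_any > 0:
            q, s = 0.0, p_any
        else:
            q = p_any * (1.0 - p_sep) / (1.0 - p_any * p_sep)
            s = p_any * p_sep
        has_cj = rng.random(n_sections) < q
        n_cj = np.zeros(n_sections, dtype=np.int64)
        if np.any(has_cj):
            n_cj[has_cj] = _zero_truncated_poisson(
                rng, np.maximum(lam[has_cj], 1e-12)
            )
        septum = rng.random(n_sections) < s

    n_septum = np.where(septum, 1 + rng.poisson(0.3, size=n_sections), 0)

    sections: list[SectionMorphometry] = []
    for i in range(n_sections):
        k = int(n_cj[i])
        diam = rng.normal(preset.diameter_mean_nm, preset.diameter_sd_nm, size=k)
        while np.any(diam <= 0):  # truncate at 0 by resampling, not clipping
            bad = diam <= 0
            diam[bad] = rng.normal(
                preset.diameter_mean_nm, preset.diameter_sd_nm, size=int(bad.sum())
            )
        sections.append(
            SectionMorphometry(
                section_id=f"{preset.condition_label}-{i:05d}",
                condition=preset.condition_label,
                om_length_um=float(lengths[i]),
                n_cj=k,
                cj_diameters_nm=tuple(np.round(diam, 3)),
                morphology_class="wild_type",
                has_septum=bool(septum[i]),
                n_septum_junctions=int(n_septum[i]),
            )
        )
    return sections


def with_seed(params: SceneParams, seed: int) -> SceneParams:
    """Copy of ``params`` with a different seed (convenience for sweeps)."""
    return replace(params, seed=seed)
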