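"""Synthetic cohorts, expression tables and gene sets with known truth.

Every downstream stage of the pipeline is testable against planted ground
truth: cohorts whose case-control difference in regional MS equals a
requested effect map, donor-level expression whose genes align with a
target cortical map by a controllable amount, and gene sets whose overlap
with a target list follows a noncentral hypergeometric law with a planted
odds ratio.

There is no closed form from feature-level shifts to regional-MS shifts,
so the cohort generator plants effects with a measure-and-rescale
calibration loop: case templates are perturbed along the direction that
raises a region's average similarity to the rest of the cortex, the
induced case-minus-control regional MS difference is measured on paired
calibration samples, and the perturbations are adjusted (via a measured
linear response model) until the shift matches the request within the
documented tolerance.

Each generator draws from its own RNG stream derived from the root seed,
so adding one generator never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DonorSampleTable
from .msnet import (
    FEATURE_NAMES,
    SubjectMorphometry,
    batch_regional_ms,
)
from .parcellation import (
    DK34_LEFT_LABELS,
    DK68_LABELS,
    fibonacci_sphere,
    generic_labels,
)

CALIBRATION_TOL = 0.10  # relative tolerance of the planted MS shift
CALIBRATION_TOL_ABS = 0.001  # absolute floor of the tolerance, MS units


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MorphSimConfig:
    n_cases: int
    n_controls: int
    n_regions: int = 68
    n_features: int = 5
    effect_map: np.ndarray | None = None  # planted shift of regional MS
    covariate_effects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.4
    seed: int = 0
    #: sub-stream for subject-level draws: cohorts sharing seed but
    #: differing here are independent samples from the same population
    #: (same latent template and planted effect), e.g. parallel studies
    #: of one clinical condition family
    subject_stream: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ConfigError("n_regions must be >= 3")
        if self.n_features < 2:
            raise ConfigError("n_features must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("need at least one subject per group")
        if self.effect_map is None:
            self.effect_map = np.zeros(self.n_regions)
        self.effect_map = np.asarray(self.effect_map, dtype=float)
        if self.effect_map.shape != (self.n_regions,):
            raise ConfigError("effect_map length must equal n_regions")


def plantable_effect_map(
    cfg: MorphSimConfig,
    lo: float = 0.005,
    hi: float = 0.014,
) -> np.ndarray:
    """Signed per-region MS shifts the cohort of ``cfg`` can realise.

    Magnitudes drawn uniformly from [lo, hi] with random signs, then
    capped by each region's own measured response slope (a region's MS
    cannot move past what the coherence of the remaining cortex supports,
    and how much headroom a region has depends on the latent template the
    seed generates). The band is large enough to dominate estimation
    noise at a few hundred subjects per group.
    """
    template = _draw_template(cfg.n_regions, cfg.n_features,
                              np.random.default_rng([cfg.seed, 1, 0]))
    pull = _pull_directions(template)
    K = _probe_response_matrix(
        template, pull, cfg.noise_sd,
        np.random.default_rng([cfg.seed, 1, 1]))
    _, proj = _truncated_pinv(K)
    rng = np.random.default_rng([cfg.seed, 4])
    mags = rng.uniform(lo, hi, size=cfg.n_regions)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_regions)
    mags = np.minimum(mags, 0.25 * np.maximum(K.diagonal(), 1e-4))
    # keep only the component the perturbation mechanism can realise
    return proj @ (mags * signs)


def _region_labels(n: int) -> tuple[str, ...]:
    if n == 68:
        return DK68_LABELS
    if n == 34:
        return DK34_LEFT_LABELS
    return generic_labels(n)


def _draw_template(
    n_regions: int, n_features: int, rng: np.random.Generator,
) -> np.ndarray:
    """Latent region x feature template with cortex-like coherence.

    Half the regions form a tight cluster around a common feature profile
    (mutually similar, like the frontal/temporal bulk of the cortex) and
    half scatter diffusely around the opposite profile (differentiated
    regions). Because the tight half is far more aligned than the diffuse
    half, coherence survives the per-subject feature standardization and
    the baseline regional MS spreads over clearly positive and negative
    values, as in real cortices — and every region retains a usable,
    monotone response to the effect-planting perturbations.
    """
    # equal weight on every feature (random signs): the per-feature
    # standardization then scales all features alike and cannot suppress
    # the coherent direction more for some seeds than others
    m = rng.choice([-1.0, 1.0], size=n_features) / np.sqrt(n_features)
    loading = rng.normal(1.0, 0.2, n_regions)
    tight = rng.permutation(n_regions) < n_regions // 2
    eps = rng.standard_normal((n_regions, n_features))
    template = np.where(
        tight[:, None], loading[:, None] * m[None, :],
        -loading[:, None] * m[None, :])
    template += np.where(tight[:, None], 0.7 * eps, 1.5 * eps)
    return template * 1.5


def _pull_directions(template: np.ndarray) -> np.ndarray:
    """Per-region unit direction that raises that region's regional MS.

    Computed on the template after the same column z-scoring / row
    centering the MS computation applies: for each region, the sum of the
    other regions' unit profiles, projected orthogonal to the region's own
    profile — the steepest-ascent direction of its mean similarity.
    Returns an (n_regions, n_features) matrix of unit directions.
    """
    z = (template - template.mean(0)) / template.std(0, ddof=1)
    c = z - z.mean(axis=1, keepdims=True)
    unit = c / np.linalg.norm(c, axis=1, keepdims=True)
    total = unit.sum(axis=0)
    directions = np.empty_like(unit)
    for j in range(unit.shape[0]):
        g = total - unit[j]
        g = g - (g @ unit[j]) * unit[j]
        norm = np.linalg.norm(g)
        directions[j] = (
            g / norm if norm > 1e-9
            else np.ones(unit.shape[1]) / np.sqrt(unit.shape[1]))
    return directions


def _measured_shift(
    template: np.ndarray,
    case_template: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    n_pairs: int = 800,
) -> np.ndarray:
    """Mean case-minus-control regional MS over paired noise draws.

    The same noise realisations are applied to both templates, so the
    difference is estimated with far less Monte-Carlo variance than two
    independent groups would give.
    """
    noise = rng.standard_normal((n_pairs, *template.shape)) * noise_sd
    ms_control = _pipeline_regional_ms(template[None] + noise)
    ms_case = _pipeline_regional_ms(case_template[None] + noise)
    return (ms_case - ms_control).mean(axis=0)


def _pipeline_regional_ms(features: np.ndarray) -> np.ndarray:
    """Regional MS of raw feature stacks, normalised exactly as the
    analysis pipeline does (per-subject column z-score, then row Pearson)."""
    mu = features.mean(axis=1, keepdims=True)
    sd = features.std(axis=1, ddof=1, keepdims=True)
    return batch_regional_ms((features - mu) / sd)


def _truncated_pinv(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-inverse of the response matrix over its well-conditioned part.

    Singular directions weaker than 0.3x the median own-response are
    dropped: they are shift patterns the perturbation mechanism cannot
    produce (most prominently a simultaneous shift of every region, since
    the total similarity budget of the network is nearly conserved).
    Returns (pinv, projector onto the attainable output subspace).
    """
    u, s, vt = np.linalg.svd(K)
    keep = s >= 0.3 * float(np.median(K.diagonal()))
    pinv = vt[keep].T @ np.diag(1.0 / s[keep]) @ u[:, keep].T
    proj = u[:, keep] @ u[:, keep].T
    return pinv, proj


def _probe_response_matrix(
    template: np.ndarray,
    pull: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    probe: float = 0.3,
    n_pairs: int = 800,
) -> np.ndarray:
    """Measured response K[j, k] = d(regional MS_j) / d(delta_k).

    An edge change is shared by both endpoints and every perturbation
    leaks into every region's mean similarity, so K is dense (and not
    symmetric: a region's own response involves all of its edges, a cross
    response only the shared one).
    """
    n = template.shape[0]
    K = np.empty((n, n))
    for j in range(n):
        d = np.zeros(n)
        d[j] = probe
        K[:, j] = _measured_shift(template, template + d[:, None] * pull,
                                  noise_sd, rng, n_pairs=n_pairs) / probe
    return K


def _calibrate_case_template(
    template: np.ndarray,
    effect_map: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    max_iter: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Find per-region perturbation magnitudes realising the planted shift.

    The delta -> shift response is a coupled, approximately linear map for
    small perturbations: the loop measures the full response matrix by
    probing each region, solves the ridge-regularised linear system for
    the requested effect map, and polishes with damped, step-limited
    Newton iterations against freshly measured shifts, keeping the best
    iterate. Tolerance: within 10% of the requested shift or 0.001 MS
    units, whichever is larger; regions that cannot reach it (a region's
    MS cannot move past what the coherence of the remaining cortex
    supports) are reported in a warning, and the achieved shifts are
    always recorded in the truth record.
    """
    pull = _pull_directions(template)
    n = template.shape[0]
    active = np.abs(effect_map) > 1e-12
    if not active.any():
        return template.copy(), np.zeros_like(effect_map)

    K = _probe_response_matrix(template, pull, noise_sd, rng)
    pinv, _ = _truncated_pinv(K)
    tol = np.maximum(CALIBRATION_TOL * np.abs(effect_map),
                     CALIBRATION_TOL_ABS)

    delta = np.clip(pinv @ effect_map, -1.2, 1.2)
    best_viol = np.inf
    best_delta = delta.copy()
    best_measured = np.zeros_like(effect_map)
    for _ in range(max_iter):
        measured = _measured_shift(template, template + delta[:, None] * pull,
                                   noise_sd, rng, n_pairs=1500)
        viol = float(np.max(np.abs(measured - effect_map) / tol))
        if viol < best_viol:
            best_viol, best_delta = viol, delta.copy()
            best_measured = measured.copy()
        if viol <= 1.0:
            break
        step = np.clip(0.7 * (pinv @ (effect_map - measured)),
                       -0.25, 0.25)
        base = best_delta if viol > 2.0 * best_viol else delta
        delta = np.clip(base + step, -1.2, 1.2)
    delta, measured = best_delta, best_measured
    n_off = int(np.sum(np.abs(measured - effect_map) > tol))
    if n_off:
        warnings.warn(
            f"calibration missed the requested shift (10% / "
            f"{CALIBRATION_TOL_ABS} tolerance) for {n_off} region(s); "
            "achieved shifts are recorded in the truth record")
    return template + delta[:, None] * pull, measured


def simulate_cohort(
    cfg: MorphSimConfig,
) -> tuple[list[SubjectMorphometry], dict]:
    """Generate a case-control cohort with a planted regional-MS shift.

    Subjects share a latent region x feature template; cases use a
    calibrated perturbed template so that the expected case-minus-control
    regional MS difference equals ``cfg.effect_map`` (within the
    calibration tolerance). Age ~ U(25, 65) years, sex ~ Bernoulli(0.5),
    ICV ~ Normal(1.5e6, 1.5e5) mm^3; the planted covariate coefficients
    shift every region's profile along the calibration direction by
    beta_age * z(age) + beta_sex * (sex - 0.5) + beta_icv * z(icv).

    Returns the subjects (cases first) and a truth record with the
    requested and achieved effect maps, calibration details and the seed.
    """
    labels = _region_labels(cfg.n_regions)
    template = _draw_template(cfg.n_regions, cfg.n_features,
                              np.random.default_rng([cfg.seed, 1, 0]))
    case_template, measured = _calibrate_case_template(
        template, cfg.effect_map, cfg.noise_sd,
        np.random.default_rng([cfg.seed, 1, 1]))
    pull = _pull_directions(template)
    rng = np.random.default_rng([cfg.seed, 1, 2, cfg.subject_stream])

    n_total = cfg.n_cases + cfg.n_controls
    age = rng.uniform(25.0, 65.0, size=n_total)
    sex = rng.integers(0, 2, size=n_total)
    icv = rng.normal(1.5e6, 1.5e5, size=n_total)
    b_age, b_sex, b_icv = cfg.covariate_effects
    cov_shift = (
        b_age * (age - 45.0) / np.sqrt((65.0 - 25.0) ** 2 / 12.0)
        + b_sex * (sex - 0.5)
        + b_icv * (icv - 1.5e6) / 1.5e5
    )

    subjects = []
    for i in range(n_total):
        is_case = i < cfg.n_cases
        base = case_template if is_case else template
        feats = (
            base
            + cov_shift[i] * pull
            + cfg.noise_sd * rng.standard_normal(base.shape)
        )
        gid = "case" if is_case else "control"
        k = i if is_case else i - cfg.n_cases
        subjects.append(SubjectMorphometry(
            subject_id=f"{gid}_{k + 1:04d}",
            group=gid,
            age=float(age[i]),
            sex=int(sex[i]),
            icv=float(icv[i]),
            features=feats,
            region_labels=labels,
            feature_names=(
                FEATURE_NAMES if cfg.n_features == len(FEATURE_NAMES)
                else tuple(f"feature_{j + 1}" for j in range(cfg.n_features))
            ),
        ))
    truth = {
        "effect_map": cfg.effect_map.copy(),
        "achieved_shift": measured,
        "covariate_effects": dict(zip(("age", "sex", "icv"),
                                      cfg.covariate_effects)),
        "covariate_model": "age~U(25,65); sex~Bernoulli(0.5); "
                           "icv~Normal(1.5e6, 1.5e5)",
        "calibration_tolerance": CALIBRATION_TOL,
        "seed": cfg.seed,
        "region_labels": labels,
    }
    return subjects, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    n_regions: int = 34
    n_donors: int = 6
    n_signal_pos: int = 100
    n_signal_neg: int = 100
    alignment_strength: float = 0.7
    donor_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_pos + self.n_signal_neg > self.n_genes:
            raise ConfigError("signal genes exceed n_genes")
        if not 0.0 <= self.alignment_strength <= 1.0:
            raise ConfigError("alignment_strength must lie in [0, 1]")
        if self.donor_noise_sd < 0:
            raise ConfigError("donor_noise_sd must be >= 0")
        if self.n_donors < 2:
            raise ConfigError("need at least 2 donors")


def toy_mm_geometry(
    n_regions: int,
    hemisphere: str = "L",
    division: str = "cortex",
    radius_mm: float = 80.0,
) -> pd.DataFrame:
    """Synthetic parcel representative points in mm for sample assignment."""
    pts = fibonacci_sphere(n_regions, hemisphere) * radius_mm
    return pd.DataFrame(
        {
            "region": _region_labels(n_regions),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "hemisphere": hemisphere,
            "division": division,
        }
    )


def simulate_expression(
    cfg: ExpressionSimConfig,
    target_map: np.ndarray,
) -> tuple[list[DonorSampleTable], pd.DataFrame, dict]:
    """Donor-level expression with genes spatially aligned to a target map.

    The first ``n_signal_pos`` genes have true regional profiles
    a * z(target) + sqrt(1 - a^2) * noise (a = alignment_strength), the
    next ``n_signal_neg`` the same with a negative sign, the rest are
    independent spatial noise. Donors are replicates of the true profile
    with additive Normal(0, donor_noise_sd) noise, one sample placed at
    each region's representative point of a synthetic geometry, one probe
    per gene, all probes above background.

    Returns (donor tables, geometry frame, truth record).
    """
    target_map = np.asarray(target_map, dtype=float)
    if target_map.shape != (cfg.n_regions,):
        raise ValueError("target_map length must equal n_regions")
    rng = np.random.default_rng([cfg.seed, 2])
    t_z = stats.zscore(target_map, ddof=1)
    a = cfg.alignment_strength

    genes = [f"gene{j + 1:05d}" for j in range(cfg.n_genes)]
    signs = np.zeros(cfg.n_genes)
    signs[: cfg.n_signal_pos] = 1.0
    signs[cfg.n_signal_pos: cfg.n_signal_pos + cfg.n_signal_neg] = -1.0
    noise = rng.standard_normal((cfg.n_regions, cfg.n_genes))
    profiles = np.where(
        signs[None, :] != 0,
        signs[None, :] * a * t_z[:, None] + np.sqrt(1.0 - a ** 2) * noise,
        noise,
    )

    geometry = toy_mm_geometry(cfg.n_regions)
    probe_ids = [f"probe_{g}" for g in genes]
    probe_to_gene = dict(zip(probe_ids, genes))
    samples = geometry[["x", "y", "z", "hemisphere", "division"]].copy()
    tables = []
    for d in range(cfg.n_donors):
        inten = profiles + cfg.donor_noise_sd * rng.standard_normal(
            profiles.shape)
        tables.append(DonorSampleTable(
            donor_id=f"donor_{d + 1}",
            samples=samples.copy(),
            intensities=inten,
            above_background=np.ones(inten.shape, dtype=bool),
            probe_ids=probe_ids,
            probe_to_gene=probe_to_gene,
        ))
    truth = {
        "profiles": pd.DataFrame(
            profiles, index=list(geometry["region"]), columns=genes),
        "signal_pos": tuple(genes[: cfg.n_signal_pos]),
        "signal_neg": tuple(
            genes[cfg.n_signal_pos: cfg.n_signal_pos + cfg.n_signal_neg]),
        "alignment_strength": a,
        "donor_noise_sd": cfg.donor_noise_sd,
        "seed": cfg.seed,
    }
    return tables, geometry, truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSetSimConfig:
    background_size: int
    set_size: int
    target_list_size: int
    planted_odds_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size > self.background_size:
            raise ConfigError("set_size must be <= background_size")
        if self.target_list_size > self.background_size:
            raise ConfigError("target_list_size must be <= background_size")
        if self.planted_odds_ratio <= 0:
            raise ConfigError("planted_odds_ratio must be > 0")


def simulate_genesets(
    cfg: GeneSetSimConfig,
) -> tuple[list[str], list[str], list[str], dict]:
    """Background, gene set and target list with a planted odds ratio.

    The overlap count is drawn from Fisher's noncentral hypergeometric
    distribution with the planted odds ratio (the central hypergeometric
    at OR = 1, so a Fisher test on the output is exactly calibrated).
    Returns (background, gene_set, target_list, truth).
    """
    rng = np.random.default_rng([cfg.seed, 3])
    background = [f"g{j + 1:06d}" for j in range(cfg.background_size)]
    set_idx = rng.choice(cfg.background_size, size=cfg.set_size,
                         replace=False)
    gene_set = [background[i] for i in sorted(set_idx)]
    max_overlap = min(cfg.set_size, cfg.target_list_size)
    min_overlap = max(0, cfg.set_size + cfg.target_list_size
                      - cfg.background_size)
    if max_overlap == 0:
        overlap = 0
    else:
        dist = stats.nchypergeom_fisher(
            cfg.background_size, cfg.set_size, cfg.target_list_size,
            cfg.planted_odds_ratio)
        overlap = int(dist.rvs(random_state=rng))
        overlap = int(np.clip(overlap, min_overlap, max_overlap))
    inside = rng.choice(set_idx, size=overlap, replace=False)
    complement = np.setdiff1d(np.arange(cfg.background_size), set_idx)
    outside = rng.choice(
        complement, size=cfg.target_list_size - overlap, replace=False)
    target = sorted(background[i] for i in np.concatenate(
        [inside, outside]).astype(int))
    truth = {
        "planted_odds_ratio": cfg.planted_odds_ratio,
        "overlap": overlap,
        "seed": cfg.seed,
    }
    return background, gene_set, target, truth
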