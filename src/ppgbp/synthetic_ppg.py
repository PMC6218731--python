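"""Synthetic 5 s PPG segments with known ground-truth blood pressure.

Each cardiac cycle is a periodized three-component pulse — an asymmetric
systolic wave with a free decay exponent (the pulse "fullness"), a dicrotic
wave riding on the decay, and a low-amplitude diastolic runoff pedestal.
The six shape parameters are solved per segment so that the *extracted*
morphology of the normalized beat (rising time, width at 25% amplitude,
pulse area) equals the value of an invertible linear map applied to the
latent (SBP, DBP); the forward model used in the solve includes the
analysis chain's Savitzky–Golay filter and sampling, so the construction
holds for measured features, filter bias included.  The widths at 50% and
75% are held at fixed ratios of the width target and are therefore
strongly collinear companions of the 25% width, which is what makes the
downstream variance-inflation-factor screening eliminate them.

The generator layers respiratory baseline wander, additive Gaussian noise
and (optionally) two artifact types — saturation plateaus and zeroed
dropouts — on top of the clean pulse train.  Beat-to-beat physiological
variability is emulated by jittering the morphology targets with standard
deviations proportional to ``noise_sd``, so a noiseless configuration is
exactly invertible: extracted features recover SBP/DBP through the inverse
morphology map up to interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .evaluation import CategoryThresholds, classify_category
from .signal_io import PPGSegment

#: Fixed systolic-peak phase within the cycle (shift-invariant after
#: periodization; kept fixed so the solver's parameters are identifiable).
SYSTOLIC_PHASE = 0.35
#: Offset of the dicrotic wave after the systolic peak (beat fraction).
DICROTIC_DELAY = 0.32
#: Dicrotic width as a multiple of the systolic fall width.
DICROTIC_WIDTH_RATIO = 1.15
#: Diastolic runoff pedestal: offset after the systolic peak and width (cycles).
PEDESTAL_DELAY = 0.48
PEDESTAL_WIDTH = 0.12
#: Dense grid length used when solving for beat-shape parameters.
SOLVER_GRID = 1500
#: Canonical 50%- and 75%-widths as fractions of the 25%-width target,
#: enforced (softly) when solving jittered beats: beat-to-beat vascular-tone
#: variability moves the whole width family together, so the higher widths
#: are modelled as deterministic companions of width_25 rather than free to
#: drift with leftover shape freedom.
WIDTH_50_RATIO = 0.63
WIDTH_75_RATIO = 0.39

#: Valid latent blood-pressure box for the default morphology map, mmHg.
SBP_RANGE = (70.0, 190.0)
DBP_RANGE = (40.0, 100.0)


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class MorphologyMap:
    """Invertible linear map (SBP, DBP) → (rising_time, width_25, area).

    ``targets = intercept + coef @ (sbp, dbp)``.  The 3×2 coefficient matrix
    has rank 2, so (SBP, DBP) is recoverable from any consistent feature
    triple via the pseudoinverse.  Defaults encode the standard qualitative
    associations — rising time shortens with systolic pressure, the
    fractional widths grow with diastolic pressure, the area tracks both
    (with a small diastolic contribution to the crest time) — with
    coefficients chosen so the whole latent box maps to feasible beat
    shapes; the area row is the centre of the beat family's attainable
    band over that box.
    """

    intercept: tuple[float, float, float] = (0.330, 0.320, 0.28081)
    coef: tuple[tuple[float, float], ...] = (
        (-0.00085, 0.0005),    # rising_time ← SBP, DBP
        (0.0, 0.00280),        # width_25   ← DBP
        (-0.0002, 0.001740),   # area       ← SBP, DBP
    )

    def __call__(self, sbp: float, dbp: float) -> np.ndarray:
        b = np.asarray(self.intercept, dtype=float)
        A = np.asarray(self.coef, dtype=float)
        return b + A @ np.array([sbp, dbp], dtype=float)

    def invert(self, rising_time: float, width_25: float, area: float) -> tuple[float, float]:
        """Recover (SBP, DBP) from a feature triple by least squares."""
        b = np.asarray(self.intercept, dtype=float)
        A = np.asarray(self.coef, dtype=float)
        y = np.array([rising_time, width_25, area], dtype=float) - b
        bp, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(bp[0]), float(bp[1])


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``category_mix`` gives the (normotensive, hypertensive, hypotensive)
    proportions of cases; ``wander_amp`` and ``noise_sd`` are fractions of the
    pulse amplitude; ``artifact_rate`` is the per-segment probability of an
    injected saturation plateau or dropout.
    """

    n_cases: int = 32
    segments_per_case: int = 30
    category_mix: tuple[float, float, float] = (0.80, 0.12, 0.08)
    heart_rate_range: tuple[float, float] = (58.0, 80.0)
    wander_freq: float = 0.25
    wander_amp: float = 0.05
    noise_sd: float = 0.01
    artifact_rate: float = 0.0
    seed: int = 0
    rate: float = 100.0
    morphology_map: MorphologyMap = field(default_factory=MorphologyMap)

    def validate(self) -> None:
        if self.n_cases < 1 or self.segments_per_case < 1:
            raise ConfigurationError("n_cases and segments_per_case must be positive")
        mix = np.asarray(self.category_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category_mix must be 3 non-negative proportions summing to 1, got {self.category_mix}"
            )
        lo, hi = self.heart_rate_range
        if not 0 < lo <= hi:
            raise ConfigurationError(f"empty heart-rate range {self.heart_rate_range}")
        if self.wander_freq >= lo / 60.0:
            raise ConfigurationError(
                f"wander_freq {self.wander_freq} Hz must stay below the slowest "
                f"heart-rate fundamental {lo / 60.0:.3g} Hz"
            )
        if self.noise_sd < 0 or self.wander_amp < 0 or not 0 <= self.artifact_rate <= 1:
            raise ConfigurationError("noise_sd/wander_amp must be >= 0, artifact_rate in [0,1]")
        # the morphology map must keep rising time and width strictly inside (0, 1)
        for sbp in SBP_RANGE:
            for dbp in DBP_RANGE:
                r, w, a = self.morphology_map(sbp, dbp)
                if not (0 < r < 1 and 0 < w < 1 and 0 < a < 1):
                    raise ConfigurationError(
                        f"morphology map leaves (0,1) at SBP={sbp}, DBP={dbp}: "
                        f"(rising_time={r:.3f}, width_25={w:.3f}, area={a:.3f})"
                    )


@dataclass
class SynthSegment:
    """A generated segment plus its ground truth."""

    segment: PPGSegment
    true_sbp: float
    true_dbp: float
    true_category: str
    artifact_flag: bool


# ---------------------------------------------------------------------------
# beat model


def _beat_profile(
    u: np.ndarray,
    rise_ratio: float,
    s_fall: float,
    a2: float,
    delay: float = DICROTIC_DELAY,
    a3: float = 0.0,
    q: float = 2.0,
) -> np.ndarray:
    """Periodized beat evaluated at cycle phase ``u`` (cycles).

    Three components: an asymmetric systolic Gaussian — rise width
    ``rise_ratio * s_fall`` on the upstroke, ``s_fall`` on the decay — which
    reproduces the fast systolic upstroke and slower diastolic runoff of a
    real PPG pulse; a symmetric dicrotic Gaussian riding on the decay,
    ``delay`` cycles later; and a broad low-amplitude diastolic runoff
    pedestal (``a3``) that adds pulse area while staying below the 25%
    amplitude level.  The decay exponent ``q`` (2 = Gaussian; larger is
    boxier) and the pedestal give the area freedom that is not already
    fixed by the rising time and the widths.
    """
    u = np.asarray(u, dtype=float)
    mu1 = SYSTOLIC_PHASE
    mu2 = mu1 + delay
    mu3 = mu1 + PEDESTAL_DELAY
    s_rise = rise_ratio * s_fall
    s2 = DICROTIC_WIDTH_RATIO * s_fall
    out = np.zeros_like(u)
    frac = np.mod(u, 1.0)
    for k in (-1.0, 0.0, 1.0):
        d1 = frac + k - mu1
        # Gaussian upstroke; fall side with a free decay exponent q — the
        # pulse "fullness" (q > 2 boxier, q < 2 peakier), which moves the
        # area at fixed fractional widths
        up = np.exp(-(d1 ** 2) / (2.0 * s_rise * s_rise))
        down = np.exp(-0.5 * np.abs(d1 / s_fall) ** q)
        out += np.where(d1 < 0.0, up, down)
        out += a2 * np.exp(-((frac + k - mu2) ** 2) / (2.0 * s2 * s2))
        out += a3 * np.exp(-((frac + k - mu3) ** 2) / (2.0 * PEDESTAL_WIDTH**2))
    return out


def _refine_extremum(x: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of a discrete extremum index."""
    n = len(x)
    if i == 0 or i == n - 1:
        return float(i)
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom == 0.0:
        return float(i)
    return i + 0.5 * (x[i - 1] - x[i + 1]) / denom


def _continuous_beat_features(
    rise_ratio: float,
    s_fall: float,
    a2: float,
    delay: float = DICROTIC_DELAY,
    n_grid: int = SOLVER_GRID,
) -> np.ndarray:
    """(rising_time, width_25, area) of the normalized periodized beat.

    Mirrors the measurement conventions of :mod:`ppgbp.features` — foot-to-foot
    beat window, min/max normalization, outermost 25% crossings — on a dense
    grid of the continuous profile, so the generator and the extractor agree
    up to discretization.
    """
    u = np.arange(n_grid) / n_grid
    f = _beat_profile(u, rise_ratio, s_fall, a2, delay)
    i_min = int(np.argmin(f))
    u0 = _refine_extremum(f, i_min) / n_grid

    v = np.arange(n_grid) / n_grid
    b = _beat_profile(u0 + v, rise_ratio, s_fall, a2, delay)
    b = (b - b.min()) / (b.max() - b.min())

    i_max = int(np.argmax(b))
    r = _refine_extremum(b, i_max) / n_grid

    level = 0.25
    above = b >= level
    first = int(np.argmax(above))
    last = n_grid - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        t_up = 0.0
    else:
        t_up = (first - 1 + (level - b[first - 1]) / (b[first] - b[first - 1])) / n_grid
    if last == n_grid - 1:
        t_down = 1.0
    else:
        t_down = (last + (b[last] - level) / (b[last] - b[last + 1])) / n_grid
    area = float(np.mean(b))
    return np.array([r, t_down - t_up, area])


@lru_cache(maxsize=8)
def _savgol_kernel(window: int, order: int) -> np.ndarray:
    from scipy.signal import savgol_coeffs

    return savgol_coeffs(window, order)


def _measured_beat_features(
    p: np.ndarray,
    period_samples: float,
    order: int = 4,
    window: int = 19,
    n_dense: int = 800,
) -> np.ndarray:
    """(rising_time, width_25, area) as the analysis chain would measure them.

    Samples the periodized beat at the given cardiac period (in samples),
    applies the same Savitzky–Golay filter as the preprocessing stage, then
    measures foot-to-foot rising time, outermost 25% width and area with
    sub-sample (parabolic / linear-interpolation) refinement.  Solving the
    beat shape against this forward model makes the generator's morphology
    targets hold for the *extracted* features, filter bias included.
    """
    L = int(np.ceil(3.0 * period_samples)) + 1
    j = np.arange(L)
    x = _beat_profile(j / period_samples, *p)
    # plain correlation with the cached kernel: only the interior (middle
    # period) is measured, so edge handling is irrelevant
    y = np.convolve(x, _savgol_kernel(window, order), mode="same")

    lo = int(np.floor(period_samples))
    hi = int(np.ceil(2.0 * period_samples)) + 1
    i0 = lo + int(np.argmin(y[lo:hi]))
    p0 = _refine_extremum(y, i0)

    pk_lo, pk_hi = i0, int(np.ceil(i0 + period_samples)) + 1
    ipk = pk_lo + int(np.argmax(y[pk_lo:pk_hi]))
    pk = _refine_extremum(y, ipk)
    r = (pk - p0) / period_samples

    v = np.interp(p0 + np.arange(n_dense) / n_dense * period_samples, j, y)
    v = (v - v.min()) / (v.max() - v.min())

    def outer_width(level: float) -> float:
        above = v >= level
        first = int(np.argmax(above))
        last = n_dense - 1 - int(np.argmax(above[::-1]))
        if first == 0:
            t_up = 0.0
        else:
            t_up = (first - 1 + (level - v[first - 1]) / (v[first] - v[first - 1])) / n_dense
        if last == n_dense - 1:
            t_down = 1.0
        else:
            t_down = (last + (v[last] - level) / (v[last] - v[last + 1])) / n_dense
        return t_down - t_up

    return np.array([r, outer_width(0.25), float(np.mean(v)), outer_width(0.50), outer_width(0.75)])


def _repin_area(shape: np.ndarray, area_target: float, period_samples: float) -> float:
    """Pedestal amplitude that restores the pulse area to its target.

    Monotone 1-D solve over the pedestal amplitude ``a3``; clipped to the
    feasible range when the target lies outside it.
    """
    from scipy.optimize import brentq

    def gap(a3: float) -> float:
        s = shape.copy()
        s[4] = a3
        return _measured_beat_features(s, period_samples)[2] - area_target

    lo_gap = gap(0.0)
    hi_gap = gap(0.25)
    if lo_gap >= 0.0:
        return 0.0
    if hi_gap <= 0.0:
        return 0.25
    return float(brentq(gap, 0.0, 0.25, xtol=1e-5))


def solve_beat_shape(
    rising_time: float,
    width_25: float,
    area: float,
    period_samples: float = 85.0,
    x0: np.ndarray | None = None,
    strict: bool = True,
    width_pins: bool = False,
    width_pin_ref: float | None = None,
) -> np.ndarray:
    """Solve the beat-shape parameters realizing the morphology targets.

    With ``strict=False`` an unreachable target triple is projected onto the
    nearest realizable beat shape instead of raising — used for jittered
    targets, where the projection is simply part of the beat-to-beat
    variability model.
    """
    target = np.array([rising_time, width_25, area], dtype=float)
    # the higher widths track a blend of the latent width trait and the
    # beat's realized width target: mostly the trait, with a partial
    # beat-to-beat co-movement
    if width_pin_ref is None:
        pin_ref = width_25
    else:
        pin_ref = 0.7 * width_pin_ref + 0.3 * width_25

    def residual(p):
        # soft terms select a canonical point of the underdetermined
        # 5-parameter solve: a systolic rise width near 0.08 cycles keeps
        # the upstroke resolvable at 100 Hz; a dicrotic summit near 0.32 of
        # the amplitude keeps the 25% width on a single crossing branch
        # (above the 25% level, below the 50% level and the beat-detection
        # threshold); and the 50% width is held at WIDTH_50_RATIO times the
        # 25%-width target, which is what makes the higher fractional widths
        # deterministic companions of width_25 rather than free to drift
        # with the remaining shape freedom
        measured = _measured_beat_features(p, period_samples)
        feats = measured[:3] - target
        grid = np.arange(400) / 400.0
        f = _beat_profile(grid, *p)
        summit = (_beat_profile(np.array([SYSTOLIC_PHASE + p[3]]), *p)[0] - f.min()) / (
            f.max() - f.min()
        )
        return np.concatenate(
            [
                feats,
                [
                    0.08 * (p[3] - DICROTIC_DELAY),
                    0.05 * (p[0] * p[1] - 0.08),
                    0.10 * (summit - 0.32),
                    0.02 * (p[5] - 2.0),
                    (1.40 * (measured[3] - WIDTH_50_RATIO * pin_ref)) if width_pins else 0.0,
                    (3.00 * (measured[4] - WIDTH_75_RATIO * pin_ref)) if width_pins else 0.0,
                ],
            ]
        )

    starts = [
        np.array([0.50, 0.12, 0.30, DICROTIC_DELAY, 0.10, 2.0]),
        np.array([0.70, 0.09, 0.25, 0.30, 0.05, 2.3]),
        np.array([0.30, 0.09, 0.12, 0.24, 0.15, 1.8]),
        np.array([0.75, 0.15, 0.45, 0.38, 0.02, 2.0]),
    ]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    # deterministic random restarts as a fallback for awkward corners
    restart_rng = np.random.default_rng(
        int(abs(rising_time * 1e4) + abs(width_25 * 1e4) * 7 + abs(area * 1e4) * 13) % (2**31)
    )
    lo = np.array([0.12, 0.03, 0.05, 0.20, 0.00, 1.50])
    hi = np.array([1.00, 0.28, 0.62, 0.44, 0.25, 3.00])
    starts += [restart_rng.uniform(lo, hi) for _ in range(20)]
    if not strict:
        # jittered targets may sit off the feasible manifold by design;
        # a short search suffices for a good projection
        starts = starts[:2]
    tol = 5e-3
    candidates: list[tuple[float, np.ndarray]] = []
    for start in starts:
        cand = least_squares(
            residual,
            start,
            bounds=(lo, hi),
            diff_step=3e-4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        candidates.append((float(np.max(np.abs(cand.fun[:3]))), cand.x))
        if candidates[-1][0] <= (tol if strict else 4.0 * tol):
            break
    candidates.sort(key=lambda c: c[0])
    best_resid, best_x = candidates[0]
    if best_resid > tol and strict:
        # derivative-free polish: the forward model has derivative kinks at
        # sample-index changes that can trap the least-squares steps
        from scipy.optimize import minimize

        for _, seed_x in candidates[:3]:
            nm = minimize(
                lambda p: float(np.sum(residual(np.clip(p, lo, hi)) ** 2)),
                seed_x,
                method="Nelder-Mead",
                options={"maxiter": 600, "xatol": 1e-10, "fatol": 1e-14},
            )
            polished = np.clip(nm.x, lo, hi)
            resid = float(np.max(np.abs(residual(polished)[:3])))
            if resid < best_resid:
                best_resid, best_x = resid, polished
            if best_resid <= tol:
                break
    if strict and best_resid > tol:
        raise ConfigurationError(
            f"no beat shape realizes targets rising_time={rising_time:.3f}, "
            f"width_25={width_25:.3f}, area={area:.3f} (residual {best_resid:.2e})"
        )
    return best_x


# ---------------------------------------------------------------------------
# blood-pressure sampling

_CATEGORIES = ("normotensive", "hypertensive", "hypotensive")

# per-category (SBP low, SBP high, DBP low, DBP high) base ranges; jitter of
# up to ±3 mmHg keeps every draw on the correct side of the 140/90/90 rules
_BP_BOXES = {
    "normotensive": (96.0, 132.0, 55.0, 84.0),
    "hypertensive": (146.0, 184.0, 72.0, 94.0),
    "hypotensive": (74.0, 86.0, 44.0, 62.0),
}
_BP_JITTER_SD = 1.5
_BP_JITTER_CLIP = 3.0

# independent morphology-target jitter per unit noise_sd (rising time,
# width_25, area): beat-to-beat variability uncorrelated across features.
# The width_25 jitter doubles as the vascular-tone variability: the solver
# holds the 50% width at a fixed ratio of the width_25 target, so the whole
# width family follows this jitter together
_TARGET_JITTER = np.array([0.40, 1.30, 0.74])


def generate_dataset(config: SynthConfig) -> list[SynthSegment]:
    """Generate ``n_cases × segments_per_case`` segments, deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    thresholds = CategoryThresholds()
    out: list[SynthSegment] = []
    n_samples = int(round(config.rate * 5.0))
    t = np.arange(n_samples) / config.rate

    # stratified case recruitment: category counts follow the requested mix
    # exactly (largest-remainder apportionment), in seeded random order
    mix = np.asarray(config.category_mix, dtype=float)
    quotas = mix * config.n_cases
    counts = np.floor(quotas).astype(int)
    for k in np.argsort(-(quotas - counts)):
        if counts.sum() >= config.n_cases:
            break
        counts[k] += 1
    case_categories = [c for c, n in zip(_CATEGORIES, counts) for _ in range(n)]
    rng.shuffle(case_categories)
    # stratified per-case pressures: within each category the base SBP and
    # DBP sit at evenly spaced quantiles of the category box (independently
    # shuffled), so the cohort spans each category's pressure range the way
    # a designed recruitment would
    base_pressures: dict[str, list[tuple[float, float]]] = {}
    for cat, n_cat in zip(_CATEGORIES, counts):
        if n_cat == 0:
            base_pressures[cat] = []
            continue
        s_lo, s_hi, d_lo, d_hi = _BP_BOXES[cat]
        quant = (np.arange(n_cat) + 0.5) / n_cat
        sbps = s_lo + quant * (s_hi - s_lo)
        dbps = d_lo + quant * (d_hi - d_lo)
        rng.shuffle(sbps)
        rng.shuffle(dbps)
        base_pressures[cat] = [(float(a), float(b)) for a, b in zip(sbps, dbps)]

    for ci in range(config.n_cases):
        case_id = f"case{ci + 1:03d}"
        category = case_categories[ci]
        base_sbp, base_dbp = base_pressures[category].pop()
        hr = rng.uniform(*config.heart_rate_range)
        period = 60.0 / hr
        amplitude = rng.uniform(0.8, 1.5)
        offset = 2.0 * amplitude
        # one canonical base solve per case; every segment starts from it so
        # the solved shape is a deterministic smooth function of its targets
        shape_guess = solve_beat_shape(
            *config.morphology_map(base_sbp, base_dbp),
            period_samples=period * config.rate,
            strict=False,
            width_pins=config.noise_sd > 0,
        )

        for si in range(config.segments_per_case):
            segment_id = f"{case_id}_s{si + 1:03d}"
            sbp = base_sbp + np.clip(rng.normal(0.0, _BP_JITTER_SD), -_BP_JITTER_CLIP, _BP_JITTER_CLIP)
            dbp = base_dbp + np.clip(rng.normal(0.0, _BP_JITTER_SD), -_BP_JITTER_CLIP, _BP_JITTER_CLIP)
            targets = config.morphology_map(sbp, dbp)
            jitter = rng.normal(0.0, _TARGET_JITTER * config.noise_sd)
            jitter = np.clip(jitter, -3 * _TARGET_JITTER * config.noise_sd,
                             3 * _TARGET_JITTER * config.noise_sd)
            targets = targets + jitter
            strict = config.noise_sd == 0.0
            shape = solve_beat_shape(
                *targets,
                period_samples=period * config.rate,
                x0=shape_guess,
                strict=strict,
                width_pins=not strict,
                # the higher widths track the pre-jitter width target: the
                # vascular-tone coupling is a trait of the latent pressure,
                # not of each beat's realized 25% width; the 50% width keeps
                # a small coupling noise of its own
                width_pin_ref=config.morphology_map(sbp, dbp)[1],
            )
            phase = rng.uniform(0.0, 1.0)
            clean = _beat_profile(t / period + phase, *shape)
            signal = offset + amplitude * clean
            if config.wander_amp > 0:
                signal = signal + config.wander_amp * amplitude * np.sin(
                    2.0 * np.pi * config.wander_freq * t + rng.uniform(0.0, 2.0 * np.pi)
                )
            if config.noise_sd > 0:
                signal = signal + rng.normal(0.0, config.noise_sd * amplitude, n_samples)

            artifact = bool(rng.random() < config.artifact_rate)
            if artifact:
                start = int(rng.integers(0, n_samples - 80))
                if rng.random() < 0.5:
                    # saturation plateau above everything else
                    signal[start : start + 80] = signal.max() + 0.3 * amplitude
                else:
                    # transducer dropout to zero (below the DC offset)
                    signal[start : start + 70] = 0.0

            seg = PPGSegment(
                case_id=case_id,
                segment_id=segment_id,
                samples=signal,
                rate=config.rate,
                ref_sbp=round(float(sbp), 1),
                ref_dbp=round(float(dbp), 1),
            )
            out.append(
                SynthSegment(
                    segment=seg,
                    true_sbp=round(float(sbp), 1),
                    true_dbp=round(float(dbp), 1),
                    true_category=classify_category(sbp, dbp, thresholds),
                    artifact_flag=artifact,
                )
            )
    return out


def category_mix_of(dataset: list[SynthSegment]) -> tuple[float, float, float]:
    """Empirical (normotensive, hypertensive, hypotensive) proportions."""
    if not dataset:
        raise ValueError("empty dataset")
    counts = {c: 0 for c in _CATEGORIES}
    for seg in dataset:
        counts[seg.true_category] += 1
    n = len(dataset)
    return tuple(counts[c] / n for c in _CATEGORIES)


def truth_table(dataset: list[SynthSegment]):
    """Sidecar ground-truth table (one row per segment)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "segment_id": [s.segment.segment_id for s in dataset],
            "case_id": [s.segment.case_id for s in dataset],
            "true_sbp": [s.true_sbp for s in dataset],
            "true_dbp": [s.true_dbp for s in dataset],
            "true_category": [s.true_category for s in dataset],
            "artifact_flag": [s.artifact_flag for s in dataset],
        }
    )
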