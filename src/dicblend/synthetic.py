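"""Synthetic blend photographs with the optical structure the analysis assumes.

The generator emulates the measurement the real experiment performs: a test
tube of an oil blend photographed against a white background, summarised as
the mean RGB of an oil patch and of an empty-tube "blank" patch directly
above it.  The generative law is Beer-Lambert-style transmittance mixing —
the per-channel optical density of a blend is linear in the blend fraction —
combined with three acquisition effects:

* a per-condition multiplicative channel gain (device x illumination color
  balance),
* a per-shot scalar brightness multiplier, log-normal, shared by the sample
  and its blank (the "lightness effect" the corrections are designed to
  cancel), and
* additive pixel noise on the 0-255 capture scale.

Numeric preset values (absorbances, gains, noise levels) are package
defaults chosen to give realistically strong but imperfect calibrations;
they are configuration, not measurements, and every one can be overridden.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataio import BlendDataset, BlendSample, as_rgb

#: Condition tag adopted for model building; the others are transfer targets.
PRIMARY_CONDITION = "SG-IA"


@dataclasses.dataclass(frozen=True)
class OpticalOil:
    """A mixture endpoint: per-channel optical density of the pure oil.

    ``absorbance`` holds one non-negative unitless density per R, G, B;
    the rendered channel is proportional to ``exp(-absorbance)``.
    """

    name: str
    absorbance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "absorbance", as_rgb(self.absorbance))
        if np.any(self.absorbance < 0):
            raise ValueError(f"oil {self.name!r}: absorbance must be >= 0 per channel")


@dataclasses.dataclass(frozen=True)
class ConditionProfile:
    """One device x illumination acquisition condition.

    ``channel_gain`` is the multiplicative color balance of the condition;
    ``lightness_jitter_sd`` is the standard deviation of the per-shot
    log-scale brightness multiplier; ``pixel_noise_sd`` is additive noise on
    the 0-255 scale.
    """

    device: str
    illumination: str
    channel_gain: np.ndarray
    lightness_jitter_sd: float = 0.0
    pixel_noise_sd: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "channel_gain", as_rgb(self.channel_gain))
        if np.any(self.channel_gain <= 0):
            raise ValueError("channel_gain must be > 0 in every channel")
        if self.lightness_jitter_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def tag(self) -> str:
        return f"{self.device}-{self.illumination}"

    def replace(self, **changes) -> "ConditionProfile":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass(frozen=True)
class SceneParams:
    """Scene geometry-free description of one mixture series.

    ``white_level`` is the blank channel value under unit gains;
    ``oils = (oil1, oil2)`` are the mixture endpoints, with the blend
    fraction weighting ``oil1``; ``clip_raw`` clips rendered channels to the
    8-bit [0, 255] range (set False for exactly log-linear data).
    """

    name: str
    oils: tuple[OpticalOil, OpticalOil]
    white_level: float = 255.0
    clip_raw: bool = True

    def __post_init__(self):
        if not 0 < self.white_level <= 255:
            raise ValueError("white_level must be in (0, 255]")

    def replace(self, **changes) -> "SceneParams":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def default_presets() -> tuple[dict[str, SceneParams], dict[str, ConditionProfile]]:
    """Default mixture scenes and the four acquisition conditions.

    Returns ``(scenes, conditions)``: scenes keyed ``"EVOO-SO"`` and
    ``"AVO-SO"`` (blend fraction = w/w soybean-oil content), conditions
    keyed by tag.  The two devices are a Moto G2 (SM) and a Galaxy S6 Edge
    (SG), each under natural (IN) and artificial (IA) lighting; SG-IA is the
    primary (model-building) condition.

    Absorbance presets encode the qualitative pigmentation ordering of the
    oils: refined soybean oil is nearly colorless, extra-virgin olive oil is
    green-dominant (green is its most transmitted channel), and avocado oil
    is the most strongly colored.
    """
    soybean = OpticalOil("SO", absorbance=(0.05, 0.03, 0.14))
    evoo = OpticalOil("EVOO", absorbance=(0.32, 0.10, 0.85))
    avocado = OpticalOil("AVO", absorbance=(0.48, 0.24, 1.05))
    scenes = {
        "EVOO-SO": SceneParams("EVOO-SO", oils=(soybean, evoo)),
        "AVO-SO": SceneParams("AVO-SO", oils=(soybean, avocado)),
    }
    conditions = {
        "SM-IN": ConditionProfile(
            "SM", "IN", channel_gain=(0.83, 0.88, 0.92),
            lightness_jitter_sd=0.05, pixel_noise_sd=2.5,
        ),
        "SM-IA": ConditionProfile(
            "SM", "IA", channel_gain=(0.87, 0.90, 0.85),
            lightness_jitter_sd=0.03, pixel_noise_sd=2.5,
        ),
        "SG-IN": ConditionProfile(
            "SG", "IN", channel_gain=(0.89, 0.91, 0.93),
            lightness_jitter_sd=0.05, pixel_noise_sd=2.0,
        ),
        "SG-IA": ConditionProfile(
            "SG", "IA", channel_gain=(0.94, 0.95, 0.92),
            lightness_jitter_sd=0.03, pixel_noise_sd=2.0,
        ),
    }
    return scenes, conditions


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_observation(
    fraction: float,
    scene: SceneParams,
    condition: ConditionProfile,
    rng: np.random.Generator,
    sample_id: str = "obs",
) -> BlendSample:
    """Render one shot: sample RGB and blank RGB for one blend fraction.

    One brightness multiplier ``g = exp(N(0, lightness_jitter_sd))`` is
    drawn per shot and applied to both the sample and its blank — the blank
    witnesses the same lighting as the sample, which is exactly the
    structure the lighting corrections exploit.  Per channel ``c``::

        blank_c  = g * gain_c * white_level + noise
        sample_c = g * gain_c * white_level * exp(-a_c(fraction)) + noise
        a_c(f)   = f * a1_c + (1 - f) * a2_c

    with independent additive ``N(0, pixel_noise_sd)`` noise per channel.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"blend fraction must lie in [0, 1], got {fraction}")
    a1, a2 = (oil.absorbance for oil in scene.oils)
    g = float(np.exp(rng.normal(0.0, condition.lightness_jitter_sd)))
    base = g * condition.channel_gain * scene.white_level
    density = fraction * a1 + (1.0 - fraction) * a2
    sample = base * np.exp(-density) + rng.normal(0.0, condition.pixel_noise_sd, 3)
    blank = base + rng.normal(0.0, condition.pixel_noise_sd, 3)
    if scene.clip_raw:
        sample = np.clip(sample, 0.0, 255.0)
        blank = np.clip(blank, 0.0, 255.0)
    return BlendSample(
        sample_id=sample_id,
        fraction=fraction,
        condition=condition.tag,
        sample_rgb=sample,
        blank_rgb=blank,
    )


def blend_fraction_grid(n_levels: int = 41) -> np.ndarray:
    """Inclusive uniform grid of blend fractions from 0 to 1.

    The default 41 levels reproduce the 0-to-100% w/w design in 2.5% steps.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    return np.linspace(0.0, 1.0, n_levels)


def generate_blend_dataset(
    scene: SceneParams,
    condition: ConditionProfile,
    n_levels: int = 41,
    replicates: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BlendDataset:
    """Render a full mixture series under one acquisition condition.

    One :class:`BlendSample` per fraction level per replicate, in fraction-
    major order.  The condition tag, mixture name and seed are recorded in
    the dataset metadata.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    fractions = blend_fraction_grid(n_levels)
    samples = []
    for i, f in enumerate(fractions):
        for r in range(replicates):
            sid = f"{scene.name}-{condition.tag}-{i:03d}" + (
                f"r{r}" if replicates > 1 else ""
            )
            samples.append(render_observation(f, scene, condition, rng, sample_id=sid))
    return BlendDataset.from_samples(
        samples,
        metadata={
            "mixture": scene.name,
            "condition": condition.tag,
            "seed": seed,
            "n_levels": n_levels,
            "replicates": replicates,
        },
    )


def apply_lighting_change(
    dataset: BlendDataset,
    gain: float | np.ndarray = 1.0,
    offset: float | np.ndarray = 0.0,
) -> BlendDataset:
    """Affine lighting perturbation: ``x -> gain * x + offset`` per channel.

    Applied identically to the sample and blank channels of every row —
    i.e. a change in the scene's lighting, not in the oils.  Useful for
    constructing transfer scenarios matched to a correction's invariance
    class (pure gains for the ratio corrections, pure offsets for the
    difference correction).
    """
    gain = np.broadcast_to(np.asarray(gain, dtype=float), (3,))
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (3,))
    frame = dataset.frame.copy()
    for cols in (("r_sample", "g_sample", "b_sample"), ("r_blank", "g_blank", "b_blank")):
        frame[list(cols)] = frame[list(cols)].to_numpy() * gain + offset
    meta = dict(dataset.metadata)
    meta["lighting_change"] = {"gain": gain.tolist(), "offset": offset.tolist()}
    return BlendDataset(frame, meta)
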