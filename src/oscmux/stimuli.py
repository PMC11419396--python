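"""Synthetic letter stimuli.

All inputs to the network are generated here: 56x56 grayscale images
containing one or more 28x28 block-letter glyphs ("A", "E", "T") placed in
quadrants, with optional per-letter luminance gains (emulating spatial
attention), additive Gaussian noise, and max-normalisation so that pixel
values span [0, 1].

The canonical training set is 132 images: 3 letters x 4 quadrants x 11 noise
standard deviations evenly spaced on [0.01, 0.25].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LETTERS: tuple[str, ...] = ("A", "E", "T")
#: label index of each letter in the output layer
LABEL_ORDER: dict[str, int] = {"A": 0, "E": 1, "T": 2}

GLYPH_SIZE = 28
IMAGE_SIZE = 56
N_QUADRANTS = 4

NOISE_SD_MIN = 0.01
NOISE_SD_MAX = 0.25
N_NOISE_LEVELS = 11

#: attention gains: attended letter, suppressed letter, neutral third letter
GAIN_ATTENDED = 1.2
GAIN_UNATTENDED = 0.8
GAIN_NEUTRAL = 1.0

_STROKE = 4  # stroke width in pixels
_GW, _GH = 20, 22  # glyph bounding box (width, height)


def _blank() -> np.ndarray:
    return np.zeros((_GH, _GW), dtype=np.uint8)


def _build_glyphs() -> dict[str, np.ndarray]:
    """Procedural block-letter bitmaps, bit-identical across runs.

    Seven-segment-style strokes of width 4 inside a 20x22 box, centered in
    the 28x28 quadrant.
    """
    w = _STROKE
    glyphs: dict[str, np.ndarray] = {}

    a = _blank()
    a[:w, :] = 1                      # top bar
    a[:, :w] = 1                      # left leg
    a[:, -w:] = 1                     # right leg
    a[10:10 + w, :] = 1               # crossbar
    glyphs["A"] = a

    e = _blank()
    e[:, :w] = 1                      # spine
    e[:w, :] = 1                      # top bar
    e[9:9 + w, :] = 1                 # middle bar
    e[-w:, :] = 1                     # bottom bar
    glyphs["E"] = e

    t = _blank()
    t[:w, :] = 1                      # top bar
    t[:, _GW // 2 - w // 2:_GW // 2 + w // 2] = 1  # stem
    glyphs["T"] = t

    out: dict[str, np.ndarray] = {}
    r0 = (GLYPH_SIZE - _GH) // 2
    c0 = (GLYPH_SIZE - _GW) // 2
    for letter, g in glyphs.items():
        canvas = np.zeros((GLYPH_SIZE, GLYPH_SIZE), dtype=np.uint8)
        canvas[r0:r0 + _GH, c0:c0 + _GW] = g
        out[letter] = canvas
    return out


_GLYPHS = _build_glyphs()


def render_glyph(letter: str) -> np.ndarray:
    """Return the 28x28 binary bitmap for ``letter``.

    Raises
    ------
    ValueError
        If ``letter`` is not one of the supported letters.
    """
    if letter not in _GLYPHS:
        raise ValueError(
            f"unsupported letter {letter!r}; valid letters are {LETTERS}"
        )
    return _GLYPHS[letter].copy()


@dataclass(frozen=True)
class Placement:
    """One letter placed in one quadrant with a luminance gain."""

    letter: str
    quadrant: int  # row-major: 0=top-left, 1=top-right, 2=bottom-left, 3=bottom-right
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.letter not in LETTERS:
            raise ValueError(
                f"unsupported letter {self.letter!r}; valid letters are {LETTERS}"
            )
        if self.quadrant not in range(N_QUADRANTS):
            raise ValueError(f"quadrant must be in 0..3, got {self.quadrant}")
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")


def _quadrant_slices(q: int) -> tuple[slice, slice]:
    row = (q // 2) * GLYPH_SIZE
    col = (q % 2) * GLYPH_SIZE
    return slice(row, row + GLYPH_SIZE), slice(col, col + GLYPH_SIZE)


def compose_image(placements: list[Placement]) -> np.ndarray:
    """Assemble the pre-noise 56x56 image from letter placements.

    Each quadrant holds ``gain * glyph`` for its placement; unfilled
    quadrants are zero.  An empty placement list yields an all-zero image.
    """
    quads = [p.quadrant for p in placements]
    if len(quads) != len(set(quads)):
        raise ValueError(f"duplicate quadrant in placements: {quads}")
    img = np.zeros((IMAGE_SIZE, IMAGE_SIZE), dtype=float)
    for p in placements:
        rs, cs = _quadrant_slices(p.quadrant)
        img[rs, cs] = p.gain * render_glyph(p.letter)
    return img


@dataclass(frozen=True)
class StimulusImage:
    """A finalized (noisy, max-normalized) stimulus.

    ``degenerate`` flags the one case where normalisation is impossible:
    an all-zero image with zero noise.
    """

    pixels: np.ndarray
    placements: tuple[Placement, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    degenerate: bool = False


def finalize_image(
    pre_noise: np.ndarray,
    noise_sd: float,
    seed: int,
    placements: tuple[Placement, ...] = (),
) -> StimulusImage:
    """Add Gaussian noise, clip negatives to 0, and max-normalize.

    The result lies in [0, 1] with max exactly 1, matching a luminance
    display range.  An all-zero input with ``noise_sd == 0`` is returned
    unchanged with ``degenerate=True`` (and a warning) to avoid dividing
    by zero.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    pixels = np.asarray(pre_noise, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None)
    peak = pixels.max()
    if peak == 0.0:
        warnings.warn("all-zero image with zero noise; skipping normalisation")
        return StimulusImage(pixels, placements, noise_sd, seed, degenerate=True)
    return StimulusImage(pixels / peak, placements, noise_sd, seed)


def make_image(
    placements: list[Placement], noise_sd: float, seed: int
) -> StimulusImage:
    """Compose and finalize in one call."""
    return finalize_image(
        compose_image(placements), noise_sd, seed, tuple(placements)
    )


@dataclass
class LabeledDataset:
    """Images paired with integer labels (label order A=0, E=1, T=2)."""

    items: list[tuple[StimulusImage, int]] = field(default_factory=list)
    label_order: tuple[str, ...] = LETTERS

    def __len__(self) -> int:
        return len(self.items)


def noise_grid() -> np.ndarray:
    """The 11 noise SDs evenly spaced on [0.01, 0.25]."""
    return np.linspace(NOISE_SD_MIN, NOISE_SD_MAX, N_NOISE_LEVELS)


def build_training_set(seed: int) -> LabeledDataset:
    """The canonical 132-image set: 3 letters x 4 quadrants x 11 noise SDs.

    Noise fields are deterministic given ``seed``; a disjoint seed gives a
    statistically fresh test set with the same composition.
    """
    # independent child seeds per image, reproducible for a given parent seed
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(
        len(LETTERS) * N_QUADRANTS * N_NOISE_LEVELS, dtype=np.uint32
    )
    ds = LabeledDataset()
    i = 0
    for letter in LETTERS:
        for quadrant in range(N_QUADRANTS):
            for sd in noise_grid():
                img = make_image(
                    [Placement(letter, quadrant)], float(sd), int(child_seeds[i])
                )
                ds.items.append((img, LABEL_ORDER[letter]))
                i += 1
    return ds


def build_competition_image(
    attended: str,
    others: list[str],
    quadrants: dict[str, int] | None = None,
    noise_sd: float = 0.10,
    seed: int = 0,
) -> StimulusImage:
    """Multi-letter image with attention gains.

    The attended letter is boosted by gain 1.2.  With one competitor the
    competitor gets 0.8.  With two competitors ``others[0]`` (unattended)
    gets 0.8 and ``others[1]`` keeps gain 1.0.
    """
    letters = [attended, *others]
    if len(set(letters)) != len(letters):
        raise ValueError(f"duplicate letter in {letters}")
    if len(letters) > 3:
        raise ValueError("at most 3 letters are defined (4 quadrants)")
    if not others:
        raise ValueError("need at least one competing letter")
    gains = {attended: GAIN_ATTENDED, others[0]: GAIN_UNATTENDED}
    if len(others) == 2:
        gains[others[1]] = GAIN_NEUTRAL
    if quadrants is None:
        quadrants = {letter: q for q, letter in enumerate(letters)}
    placements = [
        Placement(letter, quadrants[letter], gains[letter]) for letter in letters
    ]
    return make_image(placements, noise_sd, seed)
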