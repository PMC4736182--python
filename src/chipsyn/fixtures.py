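"""Seeded synthetic fixtures: sequences, scripts, chips, and well images.

Everything here is driven by a ``numpy.random.Generator`` (or an integer
seed), so fixtures are reproducible byte for byte. The generators emulate
the inputs the platform consumes:

- uniform random DNA (no composition bias, no repeats beyond chance),
  optionally with planted exact repeats or shared blocks, which is what
  the division scorer and the sharing detector key on;
- combinatorial part scripts (promoter x coding-variant libraries);
- rectangular microvalve grid chips with peripheral wells;
- chip photographs idealized as Gaussian disk wells of known amplitude on
  a dark background with additive Gaussian pixel noise.

Real chip images differ in ways that do not matter to the fixed-window
intensity math (vignetting, JPEG artifacts, reflections); tests built on
these fixtures validate the arithmetic, not a segmentation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chipcompile import ChipGraph, grid_chip

__all__ = [
    "rng_from_seed",
    "random_dna",
    "dna_with_planted_repeat",
    "targets_with_shared_block",
    "combinatorial_script",
    "random_script",
    "render_well_image",
    "WellImage",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(rng: int | np.random.Generator, length: int) -> str:
    rng = rng_from_seed(rng)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def dna_with_planted_repeat(
    rng: int | np.random.Generator,
    length: int,
    repeat_len: int,
    *,
    source_center: bool = True,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """A random sequence with an exact internal repeat.

    Copies the ``repeat_len`` bases at the sequence center (the division
    search's preferred junction region) to a second random locus. Returns
    (sequence, center span, planted copy span), spans 1-based inclusive.
    """
    rng = rng_from_seed(rng)
    seq = list(random_dna(rng, length))
    mid = length // 2
    src = (mid + 1, mid + repeat_len)  # overlap of a centered division
    if not source_center:
        src_start = int(rng.integers(0, length - repeat_len))
        src = (src_start + 1, src_start + repeat_len)
    block = "".join(seq[src[0] - 1 : src[1]])
    # drop the copy well away from the center, in the left quarter
    lo, hi = 1, max(2, length // 4 - repeat_len)
    dst_start = int(rng.integers(lo, hi))
    dst = (dst_start + 1, dst_start + repeat_len)
    seq[dst[0] - 1 : dst[1]] = block
    return "".join(seq), src, dst


def targets_with_shared_block(
    rng: int | np.random.Generator,
    n_targets: int,
    target_len: int,
    block_len: int,
) -> tuple[list[tuple[str, str]], str]:
    """Random targets that all embed one identical block (at varied offsets)."""
    rng = rng_from_seed(rng)
    block = random_dna(rng, block_len)
    targets = []
    for i in range(n_targets):
        pad = target_len - block_len
        at = int(rng.integers(0, pad + 1))
        seq = random_dna(rng, at) + block + random_dna(rng, pad - at)
        targets.append((f"t{i + 1}", seq))
    return targets, block


def combinatorial_script(
    rng: int | np.random.Generator,
    n_promoters: int = 4,
    n_coding: int = 4,
    promoter_len: int = 60,
    coding_len: int = 200,
) -> str:
    """A DSL script declaring a promoter x coding-variant library.

    Targets are all pairwise concatenations, the layout of a Golden-Gate
    style combinatorial library over a shared backbone.
    """
    rng = rng_from_seed(rng)
    lines = ["# combinatorial promoter x coding library"]
    for i in range(1, n_promoters + 1):
        lines.append(f'prom{i} = "{random_dna(rng, promoter_len)}"')
    for j in range(1, n_coding + 1):
        lines.append(f'cds{j} = "{random_dna(rng, coding_len)}"')
    names = []
    for i in range(1, n_promoters + 1):
        for j in range(1, n_coding + 1):
            name = f"var_{i}_{j}"
            lines.append(f"{name} = prom{i} + cds{j}")
            names.append(name)
    lines.append("targets = " + ", ".join(names))
    return "\n".join(lines) + "\n"


def random_script(
    rng: int | np.random.Generator,
    n_parts: int = 6,
    part_len: int = 100,
) -> str:
    """A random script exercising literals, concatenation, and slices."""
    rng = rng_from_seed(rng)
    lines = []
    names: list[str] = []
    lengths: dict[str, int] = {}
    for i in range(n_parts):
        name = f"p{i + 1}"
        if i < 2 or not names or rng.random() < 0.4:
            lines.append(f'{name} = "{random_dna(rng, part_len)}"')
            lengths[name] = part_len
        elif rng.random() < 0.5 and len(names) >= 2:
            a, b = (str(x) for x in rng.choice(names, size=2, replace=True))
            lines.append(f"{name} = {a} + {b}")
            lengths[name] = lengths[a] + lengths[b]
        else:
            a = str(rng.choice(names))
            s = int(rng.integers(1, lengths[a] + 1))
            e = int(rng.integers(s, lengths[a] + 1))
            lines.append(f"{name} = {a}[{s}-{e}]")
            lengths[name] = e - s + 1
        names.append(name)
    lines.append("targets = " + ", ".join(names[-3:]))
    return "\n".join(lines) + "\n"


@dataclass
class WellImage:
    """A rendered chip image and its ground truth."""

    pixels: np.ndarray  # float64 HxW in [0, 1], green plane
    centers: dict[str, tuple[int, int]]  # well id -> (x, y)
    amplitudes: dict[str, float]
    disk_radius: float
    noise_sigma: float


def render_well_image(
    rng: int | np.random.Generator,
    amplitudes: dict[str, float],
    *,
    grid_cols: int = 4,
    spacing: int = 60,
    margin: int = 40,
    disk_radius: float = 15.0,
    noise_sigma: float = 0.0,
) -> WellImage:
    """Render wells as flat-top Gaussian-edged disks of given peak amplitude.

    Wells sit on a regular grid. Each well's profile is ``a`` inside the
    disk radius with a Gaussian shoulder (sigma = 2 px) outside. The
    default radius (15 px) covers the corners of a centered 21 x 21
    window (max corner distance ~14.14 px), so the window mean recovers
    ``a`` exactly up to the additive noise.
    """
    rng = rng_from_seed(rng)
    ids = list(amplitudes)
    rows = (len(ids) + grid_cols - 1) // grid_cols
    h = 2 * margin + (rows - 1) * spacing + 1
    w = 2 * margin + (grid_cols - 1) * spacing + 1
    img = np.zeros((h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = {}
    for k, wid in enumerate(ids):
        r, c = divmod(k, grid_cols)
        cy, cx = margin + r * spacing, margin + c * spacing
        centers[wid] = (cx, cy)
        dist = np.hypot(yy - cy, xx - cx)
        edge = np.clip(dist - disk_radius, 0.0, None)
        img += amplitudes[wid] * np.exp(-0.5 * (edge / 2.0) ** 2)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return WellImage(img, centers, dict(amplitudes), disk_radius, noise_sigma)


def fixture_chip(rows: int = 5, cols: int = 4, **kwargs) -> ChipGraph:
    """The standard test chip: a valve grid with peripheral wells."""
    return grid_chip(rows, cols, **kwargs)
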