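"""Texture-category stimulus generation.

Two artificial texture categories ("K" and "L") are built from 12 micro-feature
tiles: 6×6 binary patterns with exactly 18 black and 18 white pixels, paired
into 6 mutually exclusive binary feature pairs. A category scheme fixes which
``k`` of the 6 pairs covary with category membership (the diagnostic features)
and which polarity of each covariant pair signals category K. Every texture is
a 30×30 grid of 900 tiles in which each of the 6 selected tile types appears
exactly 150 times, positions randomly permuted, so category information lives
only in *which* tiles are present, never in their spatial layout or frequency.

Difficulty is controlled by ``k``: with k = 6 every feature pair is diagnostic
(easiest); with k = 3 half the pairs vary randomly, independent of category
(hardest tested level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "MicroFeatureTile",
    "FeatureScheme",
    "TextureStimulus",
    "StimulusSet",
    "TrialSchedule",
    "RatingPairSet",
    "build_tiles",
    "make_scheme",
    "make_texture",
    "make_set",
    "build_schedule",
    "rasterize",
    "render_png",
    "sample_rating_pairs",
]

TILE_SIDE = 6          # pixels per tile edge
GRID_SIDE = 30         # tiles per texture edge
N_PAIRS = 6
BLACK_PER_TILE = 18    # black pixels in every tile (half of 36)
TILES_PER_TYPE = GRID_SIDE * GRID_SIDE // N_PAIRS  # 150


@dataclass(frozen=True)
class MicroFeatureTile:
    """One 6×6 binary micro-feature pattern (1 = black pixel)."""

    tile_id: int
    pair_id: int
    polarity: int
    pattern: np.ndarray

    def __post_init__(self):
        if self.tile_id != 2 * self.pair_id + self.polarity:
            raise ValueError("tile_id must equal 2*pair_id + polarity")
        if self.pattern.shape != (TILE_SIDE, TILE_SIDE):
            raise ValueError("pattern must be 6x6")
        if int(self.pattern.sum()) != BLACK_PER_TILE:
            raise ValueError("pattern must contain exactly 18 black pixels")


@dataclass(frozen=True)
class FeatureScheme:
    """Assignment of covariant feature pairs and their category-K polarities.

    ``polarity_map[pair_id]`` is the polarity that signals category K on a
    covariant pair; category L stimuli carry the complementary polarity.
    Non-covariant pairs take either polarity at random per stimulus.
    """

    k: int
    covariant_pairs: tuple
    polarity_map: dict
    seed: int

    def __post_init__(self):
        if not 0 <= self.k <= N_PAIRS:
            raise ValueError(f"k must be in 0..{N_PAIRS}, got {self.k}")
        if len(self.covariant_pairs) != self.k:
            raise ValueError("covariant_pairs size must equal k")
        if not set(self.covariant_pairs) <= set(range(N_PAIRS)):
            raise ValueError("covariant pair ids must be in 0..5")
        if set(self.polarity_map) != set(self.covariant_pairs):
            raise ValueError("polarity_map must be defined exactly on covariant pairs")

    def category_polarity(self, pair_id: int, category: str) -> int:
        pk = self.polarity_map[pair_id]
        return pk if category == "K" else 1 - pk

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "covariant_pairs": list(self.covariant_pairs),
                "polarity_map": {str(p): int(v) for p, v in self.polarity_map.items()},
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureScheme":
        d = json.loads(s)
        return cls(
            k=d["k"],
            covariant_pairs=tuple(d["covariant_pairs"]),
            polarity_map={int(p): int(v) for p, v in d["polarity_map"].items()},
            seed=d["seed"],
        )


@dataclass(frozen=True)
class TextureStimulus:
    """One categorized texture: a polarity over the 6 pairs plus a tile grid."""

    stimulus_id: str
    category: str
    polarity_vector: tuple
    grid: np.ndarray
    rendered_size: int = 275

    def __post_init__(self):
        if self.category not in ("K", "L"):
            raise ValueError("category must be 'K' or 'L'")
        if len(self.polarity_vector) != N_PAIRS:
            raise ValueError("polarity_vector must have 6 entries")
        if self.grid.shape != (GRID_SIDE, GRID_SIDE):
            raise ValueError("grid must be 30x30")

    @property
    def tile_ids(self) -> tuple:
        """The 6 tile ids selected by the polarity vector."""
        return tuple(2 * p + v for p, v in enumerate(self.polarity_vector))


@dataclass(frozen=True)
class StimulusSet:
    scheme: FeatureScheme
    stimuli: tuple
    n_per_category: int

    def __post_init__(self):
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus_ids must be unique")

    def __len__(self) -> int:
        return len(self.stimuli)

    def by_id(self, stimulus_id: str) -> TextureStimulus:
        return self._index[stimulus_id]

    @property
    def _index(self) -> dict:
        # tiny sets; rebuild on demand rather than caching on a frozen dataclass
        return {s.stimulus_id: s for s in self.stimuli}

    def manifest(self) -> pd.DataFrame:
        """Delimited-text-ready table: id, category, polarity vector."""
        return pd.DataFrame(
            {
                "stimulus_id": [s.stimulus_id for s in self.stimuli],
                "category": [s.category for s in self.stimuli],
                "polarity_vector": [
                    "".join(map(str, s.polarity_vector)) for s in self.stimuli
                ],
            }
        )


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered stimulus ids for one training session, in 100-trial blocks."""

    order: tuple
    block_size: int = 100

    def __len__(self) -> int:
        return len(self.order)

    def to_json(self) -> str:
        return json.dumps({"order": list(self.order), "block_size": self.block_size})

    @classmethod
    def from_json(cls, s: str) -> "TrialSchedule":
        d = json.loads(s)
        return cls(order=tuple(d["order"]), block_size=d["block_size"])


@dataclass(frozen=True)
class RatingPairSet:
    """40 ordered stimulus pairs for dissimilarity rating, fixed pre/post order.

    ``pair_types`` entries are "within" or "between"; within pairs additionally
    carry the shared category in ``within_category``.
    """

    pairs: tuple
    pair_types: tuple
    within_category: tuple

    def __post_init__(self):
        if not (len(self.pairs) == len(self.pair_types) == len(self.within_category)):
            raise ValueError("parallel fields must have equal length")

    def __len__(self) -> int:
        return len(self.pairs)


def build_tiles(seed: int) -> list:
    """Generate the 12 micro-feature tiles for a study, paired arbitrarily.

    Each pattern places exactly 18 black pixels uniformly at random among the
    36 cells; duplicate patterns are redrawn so all 12 are pairwise distinct.
    Tiles 2i and 2i+1 form feature pair i.
    """
    rng = substream(seed, "tiles")
    seen = set()
    patterns = []
    while len(patterns) < 2 * N_PAIRS:
        flat = np.zeros(TILE_SIDE * TILE_SIDE, dtype=np.uint8)
        flat[rng.choice(flat.size, BLACK_PER_TILE, replace=False)] = 1
        key = flat.tobytes()
        if key in seen:
            continue
        seen.add(key)
        patterns.append(flat.reshape(TILE_SIDE, TILE_SIDE))
    return [
        MicroFeatureTile(tile_id=i, pair_id=i // 2, polarity=i % 2, pattern=p)
        for i, p in enumerate(patterns)
    ]


def make_scheme(k: int, seed: int) -> FeatureScheme:
    """Fix one arbitrary combination of k covariant pairs and their K-polarities."""
    if not 0 <= k <= N_PAIRS:
        raise ValueError(f"k must be in 0..{N_PAIRS}, got {k}")
    rng = substream(seed, "scheme", k)
    pairs = tuple(sorted(rng.choice(N_PAIRS, size=k, replace=False).tolist()))
    polarity_map = {int(p): int(rng.integers(0, 2)) for p in pairs}
    return FeatureScheme(k=k, covariant_pairs=pairs, polarity_map=polarity_map, seed=seed)


def make_texture(
    scheme: FeatureScheme,
    category: str,
    seed: int,
    stimulus_id: str | None = None,
) -> TextureStimulus:
    """Generate one texture of the given category under the scheme.

    Covariant pairs take the polarity dictated by the category; the remaining
    pairs are fair coin flips. The six selected tile types each occupy exactly
    150 of the 900 grid cells, in a uniformly random arrangement.
    """
    if category not in ("K", "L"):
        raise ValueError("category must be 'K' or 'L'")
    rng = substream(seed, "texture")
    polarity = []
    for pair_id in range(N_PAIRS):
        if pair_id in scheme.polarity_map:
            polarity.append(scheme.category_polarity(pair_id, category))
        else:
            polarity.append(int(rng.integers(0, 2)))
    tile_ids = [2 * p + v for p, v in enumerate(polarity)]
    cells = np.repeat(np.array(tile_ids, dtype=np.int64), TILES_PER_TYPE)
    rng.shuffle(cells)
    return TextureStimulus(
        stimulus_id=stimulus_id if stimulus_id is not None else f"{category}-{seed}",
        category=category,
        polarity_vector=tuple(polarity),
        grid=cells.reshape(GRID_SIDE, GRID_SIDE),
    )


def make_set(scheme: FeatureScheme, n: int = 180, seed: int = 0) -> StimulusSet:
    """Generate a balanced stimulus set (n/2 per category)."""
    if n % 2 != 0:
        raise ValueError("set size must be even (equal categories)")
    stimuli = []
    for i in range(n):
        category = "K" if i < n // 2 else "L"
        idx = i if i < n // 2 else i - n // 2
        child = substream(seed, "stimulus", i)
        stimuli.append(
            make_texture(
                scheme,
                category,
                seed=int(child.integers(0, 2**31 - 1)),
                stimulus_id=f"{category}{idx:03d}",
            )
        )
    return StimulusSet(scheme=scheme, stimuli=tuple(stimuli), n_per_category=n // 2)


def build_schedule(
    stimulus_set: StimulusSet, n_trials: int = 400, seed: int = 0
) -> TrialSchedule:
    """Schedule each stimulus 2–3 times for a total of exactly ``n_trials``.

    ``n_trials − 2·|set|`` stimuli (chosen at random) are shown a third time;
    the full multiset is then uniformly shuffled.
    """
    n_stim = len(stimulus_set)
    if not 2 * n_stim <= n_trials <= 3 * n_stim:
        raise ValueError(
            f"n_trials must lie in [{2 * n_stim}, {3 * n_stim}] for {n_stim} stimuli"
        )
    rng = substream(seed, "schedule")
    ids = [s.stimulus_id for s in stimulus_set.stimuli]
    n_thrice = n_trials - 2 * n_stim
    thrice = rng.choice(n_stim, size=n_thrice, replace=False)
    order = ids * 2 + [ids[i] for i in thrice]
    order = [order[i] for i in rng.permutation(len(order))]
    return TrialSchedule(order=tuple(order))


def rasterize(texture: TextureStimulus, tiles: Sequence[MicroFeatureTile]) -> np.ndarray:
    """Render the texture to its native 180×180 binary raster (1 = black)."""
    patterns = {t.tile_id: t.pattern for t in tiles}
    rows = [
        np.hstack([patterns[tid] for tid in texture.grid[r]])
        for r in range(GRID_SIDE)
    ]
    return np.vstack(rows)


def render_png(
    texture: TextureStimulus,
    tiles: Sequence[MicroFeatureTile],
    out_path,
    final_size: int = 275,
) -> None:
    """Write the texture as a PNG, smoothly resized from 180×180 if requested."""
    from PIL import Image

    raster = rasterize(texture, tiles)
    # black pixels (1) map to intensity 0, white to 255
    img = Image.fromarray(((1 - raster) * 255).astype(np.uint8), mode="L")
    native = GRID_SIDE * TILE_SIDE
    if final_size != native:
        img = img.resize((final_size, final_size), Image.LANCZOS)
    img.save(out_path, format="PNG")


def sample_rating_pairs(stimulus_set: StimulusSet, seed: int = 0) -> RatingPairSet:
    """Draw the 40 dissimilarity pairs: 10 K–K, 10 L–L and 20 between.

    The ordered list is a deterministic function of the seed so the identical
    sequence can be presented before and after training.
    """
    ks = [s.stimulus_id for s in stimulus_set.stimuli if s.category == "K"]
    ls = [s.stimulus_id for s in stimulus_set.stimuli if s.category == "L"]
    if len(ks) < 10 or len(ls) < 10:
        raise ValueError("need at least 10 stimuli per category")
    rng = substream(seed, "rating-pairs")
    used = set()

    def draw(pool_a, pool_b):
        while True:
            a = pool_a[rng.integers(len(pool_a))]
            b = pool_b[rng.integers(len(pool_b))]
            if a == b:
                continue
            key = frozenset((a, b))
            if key in used:
                continue
            used.add(key)
            return (a, b)

    entries = []
    for _ in range(10):
        entries.append((draw(ks, ks), "within", "K"))
    for _ in range(10):
        entries.append((draw(ls, ls), "within", "L"))
    for _ in range(20):
        entries.append((draw(ks, ls), "between", ""))
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    return RatingPairSet(
        pairs=tuple(e[0] for e in entries),
        pair_types=tuple(e[1] for e in entries),
        within_category=tuple(e[2] for e in entries),
    )
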