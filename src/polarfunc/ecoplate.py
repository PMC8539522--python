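"""Community-level physiological profiling (CLPP) of 96-well carbon-source
plates.

A plate holds 31 sole-carbon-source substrates in triplicate plus 3 water
controls.  Microbial growth on a substrate reduces a tetrazolium dye and
develops purple colour; well colour intensities (from a plate photograph or
a plate-reader table) are ranked on a qualitative 0-3 scale relative to the
control wells.  Substrates where only one of the three replicates responds
are treated as false positives and excluded.  Per-substrate mean ranks feed
the community indices:

* ``AWCD`` — average well colour development, ``sum(max(n_i - c, 0)) / 31``
  over the 31 substrates, with ``n_i`` the substrate mean rank and ``c``
  the control mean (0 after control subtraction during scoring);
* Shannon ``H`` over ``p_i = n_i / sum n_j`` for used substrates;
* evenness ``J = H / ln S``; richness ``S`` = number of used substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

GROUPS = ("amino acids", "carbohydrates", "carboxylic acids", "polymers", "amines")


@dataclass(frozen=True)
class PlateLayout:
    """Maps substrates (and the water controls) to well coordinates."""

    substrate_ids: tuple[str, ...]
    group_of: dict[str, str]
    name_of: dict[str, str]
    well_positions: dict[tuple[str, int], tuple[int, int]]
    control_positions: tuple[tuple[int, int], ...]
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        n_wells = len(self.well_positions) + len(self.control_positions)
        if n_wells != self.n_rows * self.n_cols:
            raise ValueError(
                f"layout covers {n_wells} wells, expected {self.n_rows * self.n_cols}"
            )
        if len(self.substrate_ids) != 31:
            raise ValueError("expected 31 substrates")
        bad = {s for s in self.substrate_ids if self.group_of[s] not in GROUPS}
        if bad:
            raise ValueError(f"substrates with unknown group: {sorted(bad)}")


def load_layout(path=None) -> PlateLayout:
    """Load a plate layout YAML; defaults to the bundled standard catalog."""
    if path is None:
        text = (
            resources.files("polarfunc.data")
            .joinpath("ecoplate_layout.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    n_rows = int(doc.get("n_rows", 8))
    n_cols = int(doc.get("n_cols", 12))
    block_cols = int(doc.get("block_cols", 4))
    n_blocks = n_cols // block_cols
    control_pos = int(doc.get("control_position", 0))

    def well(position: int, block: int) -> tuple[int, int]:
        # column-major within each block of columns
        row = position % n_rows
        col = block * block_cols + position // n_rows
        return row, col

    substrate_ids: list[str] = []
    group_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    well_positions: dict[tuple[str, int], tuple[int, int]] = {}
    for entry in doc["substrates"]:
        code = str(entry["code"])
        substrate_ids.append(code)
        group_of[code] = str(entry["group"])
        name_of[code] = str(entry["name"])
        for b in range(n_blocks):
            well_positions[(code, b + 1)] = well(int(entry["position"]), b)
    controls = tuple(well(control_pos, b) for b in range(n_blocks))
    return PlateLayout(
        substrate_ids=tuple(substrate_ids),
        group_of=group_of,
        name_of=name_of,
        well_positions=well_positions,
        control_positions=controls,
        n_rows=n_rows,
        n_cols=n_cols,
    )


@dataclass
class WellIntensities:
    """Mean colour intensity per well on the plate grid, at one timepoint."""

    intensity: np.ndarray  # (n_rows, n_cols)
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")


def read_intensity_csv(path, timepoint: float = 0.0) -> WellIntensities:
    """Read an 8x12 (headerless) CSV of well intensities."""
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return WellIntensities(intensity=values, timepoint=timepoint)


def write_intensity_csv(wells: WellIntensities, path) -> None:
    pd.DataFrame(wells.intensity).to_csv(path, header=False, index=False)


@dataclass(frozen=True)
class PlateGeometry:
    """Grid geometry for reading well intensities off a plate photograph."""

    margin_x: int
    margin_y: int
    pitch_x: int
    pitch_y: int
    radius: int


def extract_intensities(
    image, layout: PlateLayout, geometry: PlateGeometry, timepoint: float = 0.0
) -> WellIntensities:
    """Mean channel intensity over a centred disc at each grid position.

    ``image`` is a 2-D greyscale array or anything :mod:`PIL` can open.
    Intensity is darkness: 255 minus the mean pixel value, so more colour
    development gives a larger number.
    """
    if isinstance(image, np.ndarray):
        arr = np.asarray(image, dtype=float)
    else:
        from PIL import Image

        with Image.open(image) as im:
            arr = np.asarray(im.convert("L"), dtype=float)
    h, w = arr.shape
    last_x = geometry.margin_x + (layout.n_cols - 1) * geometry.pitch_x
    last_y = geometry.margin_y + (layout.n_rows - 1) * geometry.pitch_y
    if last_x + geometry.radius >= w or last_y + geometry.radius >= h:
        raise ValueError("plate geometry exceeds image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.zeros((layout.n_rows, layout.n_cols))
    for r in range(layout.n_rows):
        for c in range(layout.n_cols):
            cx = geometry.margin_x + c * geometry.pitch_x
            cy = geometry.margin_y + r * geometry.pitch_y
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= geometry.radius**2
            out[r, c] = 255.0 - arr[disc].mean()
    return WellIntensities(intensity=out, timepoint=timepoint)


@dataclass
class PlateProfile:
    """Per-substrate mean 0-3 ranks after replicate (false-positive)
    filtering, with group means."""

    mean_score: dict[str, float]
    used: dict[str, bool]
    group_means: dict[str, float]
    replicate_scores: dict[str, tuple[int, ...]] = field(default_factory=dict)


def score_plate(
    wells: WellIntensities,
    layout: PlateLayout,
    thresholds: tuple[float, float, float],
) -> PlateProfile:
    """Rank every well 0-3 against the control mean and aggregate replicates.

    A well's rank is the number of (strictly ascending) cutoffs its
    control-subtracted intensity exceeds, clipped to [0, 3].  Substrates
    with exactly one positive replicate are false positives: their score is
    forced to 0 and they are marked unused.  Scoring is invariant to adding
    a constant to all intensities because cutoffs apply to the
    control-subtracted signal.
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be 3 strictly ascending cutoffs")
    grid = wells.intensity
    try:
        control = float(
            np.mean([grid[r, c] for r, c in layout.control_positions])
        )
    except IndexError:
        raise ValueError("control wells missing from intensity grid") from None

    def rank(value: float) -> int:
        signal = value - control
        return int(np.clip(sum(signal > cut for cut in t), 0, 3))

    mean_score: dict[str, float] = {}
    used: dict[str, bool] = {}
    replicate_scores: dict[str, tuple[int, ...]] = {}
    for sub in layout.substrate_ids:
        ranks = tuple(
            rank(grid[layout.well_positions[(sub, rep)]]) for rep in (1, 2, 3)
        )
        replicate_scores[sub] = ranks
        n_positive = sum(r > 0 for r in ranks)
        if n_positive == 1:  # false positive: one replicate only
            mean_score[sub] = 0.0
            used[sub] = False
        else:
            mean_score[sub] = float(np.mean(ranks))
            used[sub] = mean_score[sub] > 0
    group_means = {
        g: float(
            np.mean([mean_score[s] for s in layout.substrate_ids if layout.group_of[s] == g])
        )
        for g in GROUPS
    }
    return PlateProfile(
        mean_score=mean_score,
        used=used,
        group_means=group_means,
        replicate_scores=replicate_scores,
    )


def default_thresholds(
    wells: WellIntensities,
    layout: PlateLayout,
    fractions: tuple[float, float, float] = (0.15, 0.40, 0.70),
) -> tuple[float, float, float]:
    """Cutoffs at fixed fractions of the maximum control-subtracted
    intensity on the plate — a fallback when no absolute colour-to-rank
    calibration is available."""
    grid = wells.intensity
    control = float(np.mean([grid[r, c] for r, c in layout.control_positions]))
    peak = float((grid - control).max())
    if peak <= 0:
        peak = 1.0
    return tuple(f * peak for f in fractions)  # type: ignore[return-value]


def clpp_indices(profile: PlateProfile) -> dict[str, float]:
    """AWCD, Shannon ``H``, evenness ``J`` and richness ``S`` of a profile.

    With no used substrates AWCD and S are 0 and H, J are NaN.  Negative
    control-subtracted means cannot occur here (ranks are non-negative and
    controls were subtracted during scoring), but the AWCD sum floors at 0
    by construction regardless.
    """
    scores = np.array([profile.mean_score[s] for s in profile.mean_score])
    n_substrates = scores.size
    awcd = float(np.maximum(scores, 0.0).sum() / n_substrates)
    used = scores[scores > 0]
    s = int(used.size)
    if s == 0:
        return {"AWCD": 0.0, "H": float("nan"), "J": float("nan"), "S": 0}
    p = used / used.sum()
    h = float(-(p * np.log(p)).sum())
    j = float(h / np.log(s)) if s >= 2 else 0.0
    return {"AWCD": awcd, "H": h, "J": j, "S": s}
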