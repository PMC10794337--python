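"""Synthetic cohorts, scenes and bead fixtures with known ground truth.

The study design this emulates: human monocyte-derived macrophages
polarized into six phenotypes (M0; GM-CSF-M1; GM-CSF/TNFα/IFNγ-M1;
M-CSF-M2; M-CSF/IL-4-M2a; M-CSF/IL-10-M2c), imaged in four fluorescence
channels (DAPI nucleus, phalloidin/F-actin cell body, plus marker
channels such as CD80, CD163 and intracellular IL-10), with strongly
unbalanced per-class cell counts over three donors. Classes differ in
cell size, elongation and boundary irregularity, but their descriptor
distributions overlap heavily at the single-cell level — that overlap
is the condition under which class-balanced tile averaging pays off.

Every generator consumes a single ``numpy.random.default_rng(seed)``;
identical (spec, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from macromorph._geometry import DESCRIPTOR_COLUMNS, boundary_radius, polygon_descriptors

__all__ = [
    "Distribution",
    "MarkerCoupling",
    "ClassSpec",
    "SceneTruth",
    "LayoutError",
    "make_tabular_cohort",
    "make_scene",
    "make_bead_series",
    "couple_marker_to_shape",
    "dataset1_class_specs",
    "DATASET1_CLASS_SIZES",
]

#: per-class cell counts of the primary six-phenotype dataset
DATASET1_CLASS_SIZES = {
    "M0": 353,
    "GM-CSF-M1": 3078,
    "GM-CSF/TNFa/IFNg-M1": 1891,
    "M-CSF-M2": 1321,
    "M-CSF/IL-4-M2a": 1077,
    "M-CSF/IL-10-M2c": 1584,
}


@dataclass(frozen=True)
class Distribution:
    """A univariate sampling distribution (mean/sd on the natural scale)."""

    mean: float
    sd: float = 0.0
    family: str = "normal"  # normal | lognormal

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(self.mean))
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, n)
        # lognormal parameterized by natural-scale mean/sd
        var = self.sd**2
        mu = np.log(self.mean**2 / np.sqrt(self.mean**2 + var))
        sigma = np.sqrt(np.log(1.0 + var / self.mean**2))
        return rng.lognormal(mu, sigma, n)


@dataclass(frozen=True)
class MarkerCoupling:
    """Maps true cell shape to expected marker intensity.

    kind:
      * ``linear``   — intercept + sum(coefficients[d] * descriptor d)
      * ``loglinear``— intercept + sum(coefficients[d] * log descriptor d)
      * ``constant`` — intercept only
    Noise is additive Gaussian, floored at 0. Exactly one of ``noise_sd``
    (absolute) or ``noise_share`` (fraction of the realized noiseless
    variance contributed by noise) may be set; both zero/None means
    noiseless.
    """

    kind: str = "constant"
    coefficients: dict = field(default_factory=dict)
    intercept: float = 0.0
    noise_sd: float | None = None
    noise_share: float | None = None

    _KINDS = ("linear", "loglinear", "constant")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown coupling kind {self.kind!r}; known: {self._KINDS}")
        unknown = set(self.coefficients) - set(DESCRIPTOR_COLUMNS)
        if unknown:
            raise ValueError(
                f"coupling references descriptors the pipeline does not compute: {sorted(unknown)}"
            )
        if self.noise_sd is not None and self.noise_share is not None:
            raise ValueError("set noise_sd or noise_share, not both")

    def expected(self, descriptors: pd.DataFrame) -> np.ndarray:
        """Noiseless expected intensity for each row of a descriptor table."""
        out = np.full(len(descriptors), float(self.intercept))
        if self.kind == "constant":
            return out
        for name, coef in self.coefficients.items():
            vals = descriptors[name].to_numpy(dtype=float)
            out = out + coef * (np.log(vals) if self.kind == "loglinear" else vals)
        return out


@dataclass(frozen=True)
class ClassSpec:
    """One phenotype class of the synthetic cohort.

    Cell geometry is sampled as independent (area, aspect ratio,
    irregularity amplitude) draws; the ellipse semi-axes follow as
    a = sqrt(A q / (π (1 + ε²/2))), b = a/q, so minor ≤ major always
    holds, the boundary's enclosed area matches the sampled area and the
    descriptor panel is internally consistent by construction
    (aspect = major/minor, roundness ≤ 1, solidity ≤ 1). Sampling area
    and elongation independently (rather than the two axes) keeps cell
    size and cell shape separate generative factors, as in cultured-cell
    morphology where spreading area and polarization vary independently.
    """

    class_id: int
    name: str
    n_cells: int
    area_um2: Distribution
    aspect_ratio: Distribution = Distribution(1.0)
    irregularity: Distribution = Distribution(0.0)
    #: protrusion count of the boundary perturbation; a (lo, hi) pair
    #: samples uniformly per cell (cells vary in how many processes they
    #: extend), an int fixes it
    lobes: int | tuple[int, int] = (3, 8)
    marker_couplings: dict = field(default_factory=dict)  # marker name -> MarkerCoupling

    def __post_init__(self):
        if not (0 <= self.class_id <= 5):
            raise ValueError(f"class_id must be in 0..5, got {self.class_id}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")

    @property
    def expected_major_um(self) -> float:
        """First-order expected major axis, 2·sqrt(E[A]·E[q]/π)."""
        return 2.0 * np.sqrt(self.area_um2.mean * self.aspect_ratio.mean / np.pi)

    @property
    def expected_minor_um(self) -> float:
        return self.expected_major_um / self.aspect_ratio.mean

    def sample_geometry(self, rng: np.random.Generator, n: int | None = None):
        """Sample (semi-major a, semi-minor b, eps, lobes, phase)."""
        n = self.n_cells if n is None else n
        # cells below ~10 µm² or perfectly needle-thin are not resolvable
        area = np.clip(self.area_um2.sample(rng, n), 10.0, None)
        q = np.clip(self.aspect_ratio.sample(rng, n), 1.0, None)
        eps = np.clip(self.irregularity.sample(rng, n), 0.0, 0.45)
        if isinstance(self.lobes, tuple):
            lobes = rng.integers(self.lobes[0], self.lobes[1] + 1, n)
        else:
            lobes = np.full(n, int(self.lobes))
        phase = rng.uniform(0.0, 2.0 * np.pi, n)
        a = np.sqrt(area * q / (np.pi * (1.0 + eps**2 / 2.0)))
        return a, a / q, eps, lobes, phase


class LayoutError(RuntimeError):
    """Raised when scene layout cannot place a cell within the retry budget."""


@dataclass
class SceneTruth:
    """Ground truth for one simulated scene.

    ``cells`` has one row per cell: center (x right / y down, pixel
    units, origin at the top-left pixel center), semi-axes (px),
    orientation (rad), irregularity, class id, border flag, the analytic
    descriptor panel (µm units) and per-marker true per-pixel levels and
    expected integrated intensities.
    """

    cells: pd.DataFrame
    pixel_size: float
    shape: tuple[int, int]
    channel_names: list[str]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.cells.to_csv(path, index=False)
        sidecar = {
            "pixel_size": self.pixel_size,
            "shape": list(self.shape),
            "channel_names": self.channel_names,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _sample_class_table(spec: ClassSpec, rng: np.random.Generator) -> pd.DataFrame:
    a, b, eps, lobes, phase = spec.sample_geometry(rng)
    desc = polygon_descriptors(a, b, eps=eps, lobes=lobes, phase=phase)
    df = pd.DataFrame({k: desc[k] for k in DESCRIPTOR_COLUMNS})
    df.insert(0, "class_id", spec.class_id)
    return df


def make_tabular_cohort(
    specs: list[ClassSpec],
    seed: int,
    n_donors: int = 3,
    donor_sd: float = 0.03,
) -> pd.DataFrame:
    """Per-cell feature table emulating the study's single-cell data.

    One row per cell with the seven-descriptor panel plus one
    ``<marker>_norm`` column per coupled marker. Donors impose a small
    multiplicative size shift (``donor_sd`` on a unit-mean factor) on the
    sampled axes, emulating donor-to-donor variation. Deterministic for
    a fixed (specs, seed).
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    ids = [s.class_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"class_ids must be distinct, got {ids}")

    rng = np.random.default_rng(seed)
    donor_scale = 1.0 + rng.normal(0.0, donor_sd, n_donors) if donor_sd > 0 else np.ones(n_donors)

    frames = []
    for spec in specs:
        a, b, eps, lobes, phase = spec.sample_geometry(rng)
        donor = rng.integers(0, n_donors, spec.n_cells)
        scale = donor_scale[donor]
        desc = polygon_descriptors(a * scale, b * scale, eps=eps, lobes=lobes, phase=phase)
        df = pd.DataFrame({k: desc[k] for k in DESCRIPTOR_COLUMNS})
        df.insert(0, "class_id", spec.class_id)
        df.insert(1, "donor_id", donor + 1)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", np.arange(1, len(table) + 1))

    # markers: two passes so noise_share can reference pooled signal variance
    marker_names: list[str] = []
    for spec in specs:
        for m in spec.marker_couplings:
            if m not in marker_names:
                marker_names.append(m)
    expected = {}
    for marker in marker_names:
        col = np.full(len(table), np.nan)
        for spec in specs:
            if marker not in spec.marker_couplings:
                continue
            sel = (table["class_id"] == spec.class_id).to_numpy()
            col[sel] = spec.marker_couplings[marker].expected(table.loc[sel])
        expected[marker] = col
    for marker in marker_names:
        signal = expected[marker]
        pooled_var = np.nanvar(signal)
        noisy = signal.copy()
        for spec in specs:
            c = spec.marker_couplings.get(marker)
            if c is None:
                continue
            sel = (table["class_id"] == spec.class_id).to_numpy()
            sd = _resolve_noise_sd(c, pooled_var)
            if sd > 0:
                noisy[sel] = noisy[sel] + rng.normal(0.0, sd, int(sel.sum()))
        table[f"{marker}_norm"] = np.clip(noisy, 0.0, None)
    return table


def _resolve_noise_sd(coupling: MarkerCoupling, signal_var: float) -> float:
    if coupling.noise_sd is not None:
        return float(coupling.noise_sd)
    if coupling.noise_share is not None:
        share = coupling.noise_share
        if not 0.0 <= share < 1.0:
            raise ValueError(f"noise_share must be in [0, 1), got {share}")
        return float(np.sqrt(signal_var * share / (1.0 - share)))
    return 0.0


def couple_marker_to_shape(
    truth: "SceneTruth | pd.DataFrame",
    coupling: MarkerCoupling,
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell expected and noisy marker intensities from true shape.

    ``truth`` is a SceneTruth or any table carrying the descriptor
    columns. Returns a frame with ``expected`` (noiseless) and ``value``
    (noisy, floored at 0) columns. ``noise_sd`` overrides the coupling's
    own noise setting.
    """
    desc = truth.cells if isinstance(truth, SceneTruth) else truth
    rng = np.random.default_rng(seed)
    expected = coupling.expected(desc)
    sd = noise_sd if noise_sd is not None else _resolve_noise_sd(coupling, np.var(expected))
    value = expected + rng.normal(0.0, sd, len(expected)) if sd > 0 else expected.copy()
    return pd.DataFrame({"expected": expected, "value": np.clip(value, 0.0, None)})


def make_bead_series(
    slope: float,
    intercept: float,
    exposures: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_beads: int = 20,
) -> pd.DataFrame:
    """Fluorescent-bead intensity table across exposure times.

    Per exposure time (ms), ``n_beads`` intensities drawn from
    Normal(slope * exposure + intercept, noise_sd). Columns:
    exposure_ms, bead_id, intensity.
    """
    exposures = list(exposures)
    if len(set(exposures)) < 2:
        raise ValueError("need at least 2 distinct exposure times")
    rng = np.random.default_rng(seed)
    rows = []
    for exp in exposures:
        mean = slope * exp + intercept
        vals = rng.normal(mean, noise_sd, n_beads) if noise_sd > 0 else np.full(n_beads, mean)
        rows.append(
            pd.DataFrame(
                {"exposure_ms": exp, "bead_id": np.arange(1, n_beads + 1), "intensity": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# scene rendering

#: default imaging model; intensities in arbitrary camera units
SCENE_DEFAULTS = {
    "pixel_size": 0.65,  # µm/px, typical 10x objective + camera sampling
    "background": {"nucleus": 8.0, "actin": 10.0, "marker": 6.0},
    "nucleus_level": 180.0,
    "actin_level": 140.0,
    "noise_sd": 2.0,
    "nucleus_fraction": 0.35,  # nucleus radius as a fraction of the semi-minor axis
}


def make_scene(
    specs: list[ClassSpec],
    seed: int,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = SCENE_DEFAULTS["pixel_size"],
    n_cells_per_class: int | None = None,
    max_overlap: float = 0.0,
    retry_budget: int = 200,
    noise_sd: float = SCENE_DEFAULTS["noise_sd"],
    allow_border: bool = False,
) -> tuple[np.ndarray, SceneTruth]:
    """Render one multi-channel scene with full per-cell ground truth.

    Channels (axis 0): nucleus, actin, then one per marker named in the
    specs. Cell bodies are perturbed ellipses filled at a constant
    F-actin level; nuclei are disks at the cell centers; marker channels
    are filled at the cell's true per-pixel marker level. Gaussian read
    noise and a constant background are added everywhere.

    ``max_overlap`` is the tolerated fractional overlap of the bounding
    circles during placement (0 = hard non-overlap). Placement failure
    after ``retry_budget`` attempts per cell raises LayoutError.
    """
    if shape[0] <= 0 or shape[1] <= 0 or pixel_size <= 0:
        raise ValueError("image dims and pixel_size must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    marker_names: list[str] = []
    for spec in specs:
        for m in spec.marker_couplings:
            if m not in marker_names:
                marker_names.append(m)
    channel_names = ["nucleus", "actin"] + list(marker_names)

    # --- sample geometry and place cells
    records = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    for spec in specs:
        n = spec.n_cells if n_cells_per_class is None else n_cells_per_class
        a_um, b_um, eps, lobes, phase = spec.sample_geometry(rng, n)
        a_px, b_px = a_um / pixel_size, b_um / pixel_size
        theta = rng.uniform(0.0, np.pi, n)
        for i in range(n):
            rmax = a_px[i] * (1.0 + eps[i]) + 1.0
            lo_x, hi_x = (0.0, w - 1.0) if allow_border else (rmax, w - 1.0 - rmax)
            lo_y, hi_y = (0.0, h - 1.0) if allow_border else (rmax, h - 1.0 - rmax)
            if hi_x <= lo_x or hi_y <= lo_y:
                raise LayoutError(f"cell radius {rmax:.1f}px does not fit a {w}x{h} image")
            for attempt in range(retry_budget):
                cx = rng.uniform(lo_x, hi_x)
                cy = rng.uniform(lo_y, hi_y)
                ok = all(
                    np.hypot(cx - px, cy - py) >= (rmax + pr) * (1.0 - max_overlap)
                    for px, py, pr in placed
                )
                if ok:
                    break
            else:
                raise LayoutError(
                    f"could not place cell (class {spec.class_id}) after {retry_budget} attempts"
                )
            placed.append((cx, cy, rmax))
            border = bool(rmax > cx or rmax > cy or cx > w - 1 - rmax or cy > h - 1 - rmax)
            records.append(
                {
                    "cell_id": len(placed),
                    "class_id": spec.class_id,
                    "cx": cx,
                    "cy": cy,
                    "a_px": a_px[i],
                    "b_px": b_px[i],
                    "theta": theta[i],
                    "irregularity": eps[i],
                    "lobes": int(lobes[i]),
                    "phase": phase[i],
                    "border": border,
                }
            )

    cells = pd.DataFrame(
        records,
        columns=[
            "cell_id",
            "class_id",
            "cx",
            "cy",
            "a_px",
            "b_px",
            "theta",
            "irregularity",
            "lobes",
            "phase",
            "border",
        ],
    )

    # analytic descriptor truth (µm units)
    if len(cells):
        desc = polygon_descriptors(
            cells["a_px"].to_numpy() * pixel_size,
            cells["b_px"].to_numpy() * pixel_size,
            eps=cells["irregularity"].to_numpy(),
            lobes=cells["lobes"].to_numpy(),
            phase=cells["phase"].to_numpy(),
        )
        for k in DESCRIPTOR_COLUMNS:
            cells[k] = desc[k]
    else:
        for k in DESCRIPTOR_COLUMNS:
            cells[k] = pd.Series(dtype=float)

    # marker truth: per-pixel level from the class coupling (noiseless)
    spec_by_id = {s.class_id: s for s in specs}
    for marker in marker_names:
        level = np.zeros(len(cells))
        for cid, spec in spec_by_id.items():
            c = spec.marker_couplings.get(marker)
            if c is None or not len(cells):
                continue
            sel = (cells["class_id"] == cid).to_numpy()
            if sel.any():
                level[sel] = np.clip(c.expected(cells.loc[sel]), 0.0, None)
        cells[f"{marker}_level"] = level
        area_px = cells["area_um2"] / pixel_size**2 if len(cells) else pd.Series(dtype=float)
        cells[f"{marker}_total"] = level * area_px

    # --- render
    bg = SCENE_DEFAULTS["background"]
    stack = np.zeros((len(channel_names), h, w), dtype=np.float32)
    stack[0] += bg["nucleus"]
    stack[1] += bg["actin"]
    for ci in range(2, len(channel_names)):
        stack[ci] += bg["marker"]

    nuc_frac = SCENE_DEFAULTS["nucleus_fraction"]
    for row in cells.itertuples(index=False):
        body = _raster_cell(row, shape)
        ys, xs = body
        stack[1][ys, xs] += SCENE_DEFAULTS["actin_level"]
        for ci, marker in enumerate(marker_names, start=2):
            stack[ci][ys, xs] += getattr(row, f"{marker}_level")
        # nucleus disk
        rn = max(2.0, nuc_frac * row.b_px)
        yy, xx = _disk_pixels(row.cx, row.cy, rn, shape)
        stack[0][yy, xx] += SCENE_DEFAULTS["nucleus_level"]

    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)
        np.clip(stack, 0.0, None, out=stack)

    truth = SceneTruth(cells=cells, pixel_size=pixel_size, shape=(h, w), channel_names=channel_names)
    return stack, truth


def _raster_cell(row, shape: tuple[int, int]):
    """Pixel-center indices (ys, xs) inside one perturbed-ellipse cell."""
    h, w = shape
    rmax = row.a_px * (1.0 + row.irregularity) + 1.0
    x0, x1 = max(0, int(np.floor(row.cx - rmax))), min(w - 1, int(np.ceil(row.cx + rmax)))
    y0, y1 = max(0, int(np.floor(row.cy - rmax))), min(h - 1, int(np.ceil(row.cy + rmax)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xx - row.cx
    dy = yy - row.cy
    ct, st = np.cos(row.theta), np.sin(row.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    inside = rho <= boundary_radius(ang, row.a_px, row.b_px, row.irregularity, row.lobes, row.phase)
    return yy[inside], xx[inside]


def _disk_pixels(cx: float, cy: float, r: float, shape: tuple[int, int]):
    h, w = shape
    x0, x1 = max(0, int(np.floor(cx - r))), min(w - 1, int(np.ceil(cx + r)))
    y0, y1 = max(0, int(np.floor(cy - r))), min(h - 1, int(np.ceil(cy + r)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return yy[inside], xx[inside]


def write_scene_tiff(path: str | Path, stack: np.ndarray, truth: SceneTruth) -> None:
    """Write the scene as a multi-page TIFF (one page per channel)."""
    tifffile.imwrite(
        path,
        stack,
        metadata={"axes": "CYX", "channel_names": truth.channel_names,
                  "pixel_size_um": truth.pixel_size},
    )


def read_scene_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# default six-class study emulation


def _default_marker_couplings(kind: str) -> dict:
    """Marker couplings for one phenotype template.

    IL-10 is purely morphology-coupled (identical across classes), the
    construction behind the morphology-only IL-10 regression: linear in
    area, major axis and aspect ratio with coefficients balanced so each
    of the three contributes comparable variance, at a 5% noise share.
    CD80 is elevated in M1-like classes, CD163 in M2-like classes, each
    with a mild size coupling and absolute noise.
    """
    il10 = MarkerCoupling(
        kind="linear",
        coefficients={"area_um2": 0.004, "major_um": 0.10, "aspect_ratio": 2.0},
        intercept=1.0,
        noise_share=0.05,
    )
    m1 = kind in ("m1", "m1_stim")
    cd80 = MarkerCoupling(
        kind="linear",
        coefficients={"area_um2": 0.001},
        intercept=6.0 if m1 else 2.0,
        noise_sd=1.0,
    )
    cd163 = MarkerCoupling(
        kind="linear",
        coefficients={"area_um2": 0.001},
        intercept=2.0 if m1 else 5.5,
        noise_sd=1.0,
    )
    return {"cd80": cd80, "cd163": cd163, "il10": il10}


def dataset1_class_specs(scale: float = 1.0) -> list[ClassSpec]:
    """The default six-phenotype cohort specification.

    Class sizes are the study's per-class cell counts (total 9304 cells
    over 3 donors). Geometry means follow the reported morphology
    ordering (M1-stimulated and M2a cells elongated, M0/M-CSF-M2 small
    and round) with within-class spreads wide enough that single-cell
    descriptor distributions overlap heavily across classes.
    ``scale`` < 1 shrinks every class size proportionally (minimum 2)
    for quick runs.
    """

    def n(name):
        return max(2, int(round(DATASET1_CLASS_SIZES[name] * scale)))

    geo = {
        # name: (area mean µm², aspect mean, irregularity mean, kind)
        "M0": (330.0, 1.30, 0.05, "m0"),
        "GM-CSF-M1": (520.0, 1.40, 0.10, "m1"),
        "GM-CSF/TNFa/IFNg-M1": (600.0, 1.75, 0.18, "m1_stim"),
        "M-CSF-M2": (450.0, 1.26, 0.07, "m2"),
        "M-CSF/IL-4-M2a": (760.0, 1.70, 0.22, "m2a"),
        "M-CSF/IL-10-M2c": (700.0, 1.38, 0.12, "m2c"),
    }
    specs = []
    for cid, (name, (area, aspect, irr, kind)) in enumerate(geo.items()):
        specs.append(
            ClassSpec(
                class_id=cid,
                name=name,
                n_cells=n(name),
                area_um2=Distribution(area, 0.45 * area, "lognormal"),
                aspect_ratio=Distribution(aspect, 0.15 * aspect, "lognormal"),
                irregularity=Distribution(irr, 0.12),
                marker_couplings=_default_marker_couplings(kind),
            )
        )
    return specs
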