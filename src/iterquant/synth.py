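"""Synthetic plate images and amplicon read sets with known ground truth.

Emulates the acquisition geometry of an arrayed protoplast transfection
screen: a 96-well plate, 9 fields of view per well, 7 Z-planes and 4 channels
(brightfield, chlorophyll, GFP, mCherry).  Protoplasts are rendered as round
discs — with chlorophyll autofluorescence in wheat mode, without in etiolated
maize mode.  Transfected cells carry a nuclear mCherry disc and edited cells
additionally a nuclear GFP disc, so every downstream segmentation and gating
stage can be checked against an exact truth table.

Amplicon read sets are generated as single full-length, pre-merged reads from
a mixture of haplotypes (substitutions and/or one indel) with configurable
allele fractions, per-base error rate and Phred qualities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as iqio
from .amplicon import AmpliconTarget, _revcomp
from .errors import ConfigurationError, InputError, LayoutError
from .hci import MAIZE, WHEAT, ChannelStack

BASES = np.array(list("ACGT"))

# minimum centre separation between rendered cells, in units of mean radius
MIN_SEPARATION_FACTOR = 2.2


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class WellCondition:
    """What one well contains: a construct, its replicate group and the
    ground-truth transfection/editing rates of the cells plated in it."""

    construct: str = "construct"
    replicate_group: str = ""
    control: bool = False
    n_cells: int = 150
    transfection_rate: float = 0.5
    editing_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("transfection_rate", "editing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.control:
            # no DNA delivered: nothing can be transfected or edited
            self.transfection_rate = 0.0
            self.editing_rate = 0.0


@dataclass
class ChannelModel:
    """Foreground/background intensity model of one channel (16-bit units)."""

    foreground_mean: float
    foreground_sd: float
    background: float
    noise_sd: float


DEFAULT_CHANNEL_MODELS: dict[str, ChannelModel] = {
    "brightfield": ChannelModel(-2000.0, 200.0, 12000.0, 30.0),
    "chlorophyll": ChannelModel(1500.0, 250.0, 200.0, 15.0),
    "GFP": ChannelModel(3000.0, 500.0, 200.0, 15.0),
    "mCherry": ChannelModel(3000.0, 500.0, 200.0, 15.0),
}


@dataclass
class SimulationConfig:
    """Full description of a simulated plate acquisition."""

    wells: dict[str, WellCondition]
    plate_shape: tuple[int, int] = (8, 12)
    fields_per_well: int = 9
    z_planes: int = 7
    field_size: tuple[int, int] = (512, 512)
    species_mode: str = WHEAT
    cell_radius: tuple[float, float] = (20.0, 2.5)  # mean, sd in px
    nucleus_radius: tuple[float, float] = (7.0, 1.0)
    channel_models: dict[str, ChannelModel] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MODELS)
    )
    vignetting_strength: float = 0.3
    debris_count: int = 2
    z_profile_sigma: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fields_per_well < 1 or self.z_planes < 1:
            raise ConfigurationError("fields_per_well and z_planes must be >= 1")
        if self.cell_radius[0] <= 0 or self.nucleus_radius[0] <= 0:
            raise ConfigurationError("radii must be positive")
        if self.nucleus_radius[0] >= self.cell_radius[0]:
            raise ConfigurationError("nucleus radius must be smaller than cell radius")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ConfigurationError("vignetting strength must be in [0, 1)")
        if self.species_mode not in (WHEAT, MAIZE):
            raise ConfigurationError(f"unknown species mode {self.species_mode!r}")
        for well in self.wells:
            iqio.parse_well(well, self.plate_shape)

    def well_rng(self, well: str, field_index: int) -> np.random.Generator:
        """Counter-derived substream: stable under partial regeneration."""
        row, col = iqio.parse_well(well, self.plate_shape)
        well_index = row * self.plate_shape[1] + col
        ss = np.random.SeedSequence(self.rng_seed, spawn_key=(well_index, field_index))
        return np.random.default_rng(ss)


def default_plate_config(
    seed: int = 0,
    n_conditions: int = 4,
    replicates: int = 3,
    n_cells: int = 150,
    transfection_rate: float = 0.5,
    editing_rates: tuple[float, ...] = (0.02, 0.1, 0.3, 0.5),
    species_mode: str = WHEAT,
    fields_per_well: int = 9,
) -> SimulationConfig:
    """A small demo layout: conditions in columns, one control column."""
    wells: dict[str, WellCondition] = {}
    for c in range(n_conditions):
        rate = editing_rates[c % len(editing_rates)]
        for r in range(replicates):
            wells[iqio.well_name(r, c)] = WellCondition(
                construct=f"BE_v{c + 1}",
                replicate_group=f"rep{r + 1}",
                n_cells=n_cells,
                transfection_rate=transfection_rate,
                editing_rate=rate,
            )
    for r in range(replicates):
        wells[iqio.well_name(r, n_conditions)] = WellCondition(
            construct="no_DNA", control=True, n_cells=n_cells
        )
    return SimulationConfig(
        wells=wells, rng_seed=seed, species_mode=species_mode,
        fields_per_well=fields_per_well,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthCell:
    """Truth record for one rendered object."""

    well: str
    field: int
    x: float
    y: float
    radius: float
    is_transfected: bool
    is_edited: bool
    is_debris: bool = False

    def __post_init__(self) -> None:
        if self.is_edited and not self.is_transfected:
            raise ValueError("edited implies transfected")
        if self.is_debris and self.is_transfected:
            raise ValueError("debris is never transfected")


def _cells_in_field(n_total: int, fields: int, field_index: int) -> int:
    base, extra = divmod(n_total, fields)
    return base + (1 if field_index < extra else 0)


def _sample_positive(rng, mean: float, sd: float) -> float:
    # negative draws are resampled, never rendered
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
) -> list[tuple[float, float]]:
    """Non-overlapping positions by rejection sampling (dilute suspension)."""
    centers: list[tuple[float, float]] = []
    if n == 0:
        return centers
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ConfigurationError("field too small for the configured cell radius")
    attempts = 0
    max_attempts = 500 * max(n, 1)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigurationError(
                f"could not place {n} cells at min distance {min_dist:.1f}px "
                f"in a {h}x{w} field; lower the density"
            )
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_dist**2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def field_truth(
    config: SimulationConfig,
    well: str,
    field_index: int,
    rng: np.random.Generator,
) -> list[GroundTruthCell]:
    """Draw positions, radii and transfection/editing flags for one field."""
    if well not in config.wells:
        raise LayoutError(f"well {well!r} not in the condition map")
    if not 0 <= field_index < config.fields_per_well:
        raise InputError(f"field index {field_index} outside 0..{config.fields_per_well - 1}")
    cond = config.wells[well]
    n = _cells_in_field(cond.n_cells, config.fields_per_well, field_index)
    mean_r, sd_r = config.cell_radius
    margin = mean_r + 3 * sd_r + 2
    centers = _place_centers(
        rng, n, config.field_size, margin, MIN_SEPARATION_FACTOR * mean_r
    )
    cells = []
    for y, x in centers:
        radius = _sample_positive(rng, mean_r, sd_r)
        transfected = bool(rng.random() < cond.transfection_rate)
        edited = transfected and bool(rng.random() < cond.editing_rate)
        cells.append(
            GroundTruthCell(
                well=well, field=field_index, x=x, y=y, radius=radius,
                is_transfected=transfected, is_edited=edited,
            )
        )
    return cells


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table for the whole plate without rendering any pixels.

    Uses the same per-well/per-field substreams as :func:`simulate_field`, so
    the counts-level simulation and the rendered one agree cell for cell.
    """
    rows = []
    for well in sorted(config.wells, key=lambda w: iqio.parse_well(w, config.plate_shape)):
        for f in range(config.fields_per_well):
            rng = config.well_rng(well, f)
            for cell in field_truth(config, well, f, rng):
                rows.append(cell.__dict__.copy())
    return pd.DataFrame(
        rows,
        columns=[
            "well", "field", "x", "y", "radius",
            "is_transfected", "is_edited", "is_debris",
        ],
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _disc_mask(shape, cy, cx, radius):
    y0 = max(0, int(cy - radius) - 1)
    y1 = min(shape[0], int(cy + radius) + 2)
    x0 = max(0, int(cx - radius) - 1)
    x1 = min(shape[1], int(cx + radius) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return (slice(y0, y1), slice(x0, x1)), mask


def _ellipse_mask(shape, cy, cx, a, b, theta):
    r = int(max(a, b)) + 2
    y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (yy - cy) * ct + (xx - cx) * st
    v = -(yy - cy) * st + (xx - cx) * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), mask


def _vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - strength * r2


def simulate_field(
    config: SimulationConfig,
    well: str,
    field_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelStack, list[GroundTruthCell]]:
    """Render one field of view and return it with its truth list.

    The stack has 4 channels x ``z_planes`` planes.  Cells are discs; the
    chlorophyll channel carries cell-body signal only in wheat mode.
    Transfected cells get a nuclear mCherry disc and edited cells a nuclear
    GFP disc.  Debris objects are elongated ellipses with chlorophyll-like
    intensity and no nuclear signal.  Object intensity follows a Gaussian
    profile across Z with its maximum at a random focal plane, and a radial
    vignette is applied multiplicatively before noise.
    """
    if rng is None:
        rng = config.well_rng(well, field_index)
    cells = field_truth(config, well, field_index, rng)

    shape = config.field_size
    z = config.z_planes
    planes = {
        ch: np.zeros((z, *shape), dtype=float) for ch in config.channel_models
    }
    z_idx = np.arange(z)

    def z_weights() -> np.ndarray:
        focal = rng.integers(0, z)
        return np.exp(-0.5 * ((z_idx - focal) / config.z_profile_sigma) ** 2)

    def paint(channel: str, region, mask, amplitude: float, weights: np.ndarray) -> None:
        planes[channel][(slice(None), *region)][:, mask] += amplitude * weights[:, None]

    mean_nr, sd_nr = config.nucleus_radius
    models = config.channel_models
    for cell in cells:
        w_z = z_weights()
        region, mask = _disc_mask(shape, cell.y, cell.x, cell.radius)
        if config.species_mode == WHEAT:
            amp = _sample_positive(rng, models["chlorophyll"].foreground_mean,
                                   models["chlorophyll"].foreground_sd)
            paint("chlorophyll", region, mask, amp, w_z)
        paint("brightfield", region, mask, models["brightfield"].foreground_mean, w_z)
        if cell.is_transfected:
            nr = min(_sample_positive(rng, mean_nr, sd_nr), 0.8 * cell.radius)
            nregion, nmask = _disc_mask(shape, cell.y, cell.x, nr)
            amp = _sample_positive(rng, models["mCherry"].foreground_mean,
                                   models["mCherry"].foreground_sd)
            paint("mCherry", nregion, nmask, amp, w_z)
            if cell.is_edited:
                amp = _sample_positive(rng, models["GFP"].foreground_mean,
                                       models["GFP"].foreground_sd)
                paint("GFP", nregion, nmask, amp, w_z)

    debris_truth = []
    mean_r = config.cell_radius[0]
    cell_centers = [(c.y, c.x) for c in cells]
    for _ in range(config.debris_count):
        w_z = z_weights()
        a = rng.uniform(2.0, 4.0) * mean_r  # elongated streaks
        b = rng.uniform(0.2, 0.4) * mean_r
        # keep debris clear of cells so truth matching stays unambiguous
        clearance = a + 1.3 * mean_r
        for _ in range(500):
            cy = rng.uniform(0, shape[0])
            cx = rng.uniform(0, shape[1])
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 >= clearance**2 for y, x in cell_centers
            ):
                break
        else:
            continue  # field too crowded for more debris
        cell_centers.append((cy, cx))
        theta = rng.uniform(0, math.pi)
        region, mask = _ellipse_mask(shape, cy, cx, a, b, theta)
        if config.species_mode == WHEAT:
            amp = _sample_positive(rng, models["chlorophyll"].foreground_mean,
                                   models["chlorophyll"].foreground_sd)
            paint("chlorophyll", region, mask, amp, w_z)
        paint("brightfield", region, mask, models["brightfield"].foreground_mean, w_z)
        debris_truth.append(
            GroundTruthCell(
                well=well, field=field_index, x=cx, y=cy, radius=a,
                is_transfected=False, is_edited=False, is_debris=True,
            )
        )

    vignette = _vignette(shape, config.vignetting_strength)
    channels = {}
    for ch, model in models.items():
        img = (planes[ch] + model.background) * vignette[None, :, :]
        if model.noise_sd > 0:
            img = img + rng.normal(0.0, model.noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0, 65535).astype(np.uint16)

    stack = ChannelStack(well=well, field=field_index, channels=channels)
    return stack, cells + debris_truth


def simulate_plate(
    config: SimulationConfig,
    outdir,
    overwrite: bool = False,
) -> dict:
    """Render every field of the plate to disk and return a manifest.

    Writes one multi-page TIFF per field, the layout and truth tables as CSV,
    and ``manifest.json``.  Re-running with the same seed reproduces an
    identical truth table.
    """
    from pathlib import Path

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigurationError(f"output dir {outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    truth_rows = []
    image_paths = []
    wells = sorted(config.wells, key=lambda w: iqio.parse_well(w, config.plate_shape))
    for well in wells:
        for f in range(config.fields_per_well):
            stack, truth = simulate_field(config, well, f)
            path = outdir / f"{well}_f{f}.tiff"
            iqio.write_stack(stack, path)
            image_paths.append(path.name)
            truth_rows.extend(t.__dict__.copy() for t in truth)

    truth = pd.DataFrame(
        truth_rows,
        columns=["well", "field", "x", "y", "radius",
                 "is_transfected", "is_edited", "is_debris"],
    )
    truth.to_csv(outdir / "truth.csv", index=False)

    layout = pd.DataFrame(
        {
            "well": wells,
            "condition": [config.wells[w].construct for w in wells],
            "replicate_group": [config.wells[w].replicate_group for w in wells],
            "control_role": [
                "no_guide_control" if config.wells[w].control else "none" for w in wells
            ],
            "species_mode": config.species_mode,
        }
    )
    iqio.write_layout(layout, outdir / "layout.csv")

    manifest = {
        "seed": config.rng_seed,
        "species_mode": config.species_mode,
        "fields": image_paths,
        "layout": "layout.csv",
        "truth": "truth.csv",
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """One allele of the amplicon: substitutions and/or a single indel.

    Coordinates are 0-based on the amplicon.  ``substitutions`` is a sequence
    of (position, new base); ``deletion`` is (start, length); ``insertion`` is
    (position, inserted sequence) placed before that position.
    """

    name: str = "reference"
    substitutions: tuple[tuple[int, str], ...] = ()
    deletion: tuple[int, int] | None = None
    insertion: tuple[int, str] | None = None

    def apply(self, amplicon: str) -> str:
        seq = list(amplicon)
        for pos, base in self.substitutions:
            if not 0 <= pos < len(amplicon):
                raise InputError(f"substitution at {pos} outside amplicon")
            seq[pos] = base.upper()
        if self.deletion is not None:
            start, length = self.deletion
            if start < 0 or start + length > len(amplicon):
                raise InputError("deletion extends past amplicon")
            seq[start : start + length] = []
        if self.insertion is not None:
            pos, ins = self.insertion
            if not 0 <= pos <= len(amplicon):
                raise InputError("insertion outside amplicon")
            # apply after deletion bookkeeping only when they do not overlap
            offset = 0
            if self.deletion is not None and pos >= self.deletion[0] + self.deletion[1]:
                offset = -self.deletion[1]
            seq[pos + offset : pos + offset] = list(ins.upper())
        return "".join(seq)


@dataclass
class AlleleSpec:
    """A mixture of haplotypes with an error and quality model."""

    haplotypes: tuple[tuple[Haplotype, float], ...]
    per_base_error: float = 0.0
    quality_mean: float = 36.0
    quality_sd: float = 0.0
    allocation: str = "deterministic_counts"  # or "multinomial"
    revcomp_prob: float = 0.0
    index: str | None = None  # optional 6-nt inline index prefix

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"haplotype fractions sum to {total}, not 1")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ConfigurationError("per-base error must be in [0, 1)")
        if self.allocation not in ("deterministic_counts", "multinomial"):
            raise ConfigurationError(f"unknown allocation mode {self.allocation!r}")
        if self.index is not None and len(self.index) != 6:
            raise ConfigurationError("inline index must be 6 nt")


def _haplotype_counts(spec: AlleleSpec, n_reads: int, rng) -> list[int]:
    fractions = [f for _, f in spec.haplotypes]
    if spec.allocation == "multinomial":
        return list(rng.multinomial(n_reads, fractions))
    counts = [round(f * n_reads) for f in fractions]
    # rounding drift goes to the most abundant haplotype
    diff = n_reads - sum(counts)
    counts[int(np.argmax(fractions))] += diff
    return counts


def simulate_reads(
    target: AmpliconTarget,
    spec: AlleleSpec,
    n_reads: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
):
    """Generate full-amplicon reads from an allele mixture.

    In ``deterministic_counts`` mode each haplotype receives exactly
    ``round(fraction * n_reads)`` reads.  Sequencing noise substitutes each
    base independently with probability ``per_base_error``; qualities are
    drawn from N(quality_mean, quality_sd), clipped to [2, 41] and encoded
    Phred+33.  Reads are emitted grouped by haplotype in deterministic order and
    optionally reverse-complemented with probability ``revcomp_prob`` or
    prefixed with a 6-nt inline index.
    """
    if n_reads < 1:
        raise InputError("n_reads must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = _haplotype_counts(spec, n_reads, rng)
    reads = []
    read_no = 0
    for (hap, _), count in zip(spec.haplotypes, counts):
        hap_seq = hap.apply(target.amplicon)
        for _ in range(count):
            seq = np.array(list(hap_seq))
            if spec.per_base_error > 0:
                err = rng.random(len(seq)) < spec.per_base_error
                if err.any():
                    # substitute with a uniformly chosen different base
                    originals = seq[err]
                    subs = BASES[rng.integers(0, 4, size=int(err.sum()))]
                    clash = subs == originals
                    while clash.any():
                        subs[clash] = BASES[rng.integers(0, 4, size=int(clash.sum()))]
                        clash = subs == originals
                    seq[err] = subs
            read_seq = "".join(seq)
            quals = np.clip(
                np.rint(rng.normal(spec.quality_mean, spec.quality_sd, len(read_seq))),
                2, 41,
            ).astype(int)
            qual = "".join(chr(int(q) + 33) for q in quals)
            if spec.revcomp_prob > 0 and rng.random() < spec.revcomp_prob:
                read_seq = _revcomp(read_seq)
                qual = qual[::-1]
            if spec.index is not None:
                read_seq = spec.index.upper() + read_seq
                qual = "I" * 6 + qual  # Q40 index bases
            reads.append(
                iqio.FastqRead(f"{target.target_id}_{hap.name}_{read_no}", read_seq, qual)
            )
            read_no += 1
    return reads
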