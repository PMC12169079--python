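"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the statistical structure the analysis assumes:

* :func:`generate_repertoire_pair` — a pair of clonotype tables (biopsy /
  explant style) with forced top-clone frequencies, a controlled number of
  shared clones and a power-law tail;
* :func:`generate_tissue` — a lobule/portal-tract raster geometry with
  sinusoid channels and bile ducts;
* :func:`generate_cells` — zone-wise homogeneous Poisson cell placement
  with clone-labelled CD8 cells optionally enriched at the portal
  interface;
* :func:`generate_transcripts` — per-cell Poisson transcript counts with a
  controlled nearest-neighbour bleed-through rate.

Each generator records its ground truth in a :class:`GroundTruthManifest`
so every downstream recovery test can be scored without re-simulation.
One global seed fans out to fixed per-stage child seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import draw as skdraw
from skimage import morphology

from .zonation import MaskBundle, Zone, ZoneMap, TISSUE_ZONES

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
TRBV_GENES = tuple(f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 11, 12, 19, 20, 27, 28, 29, 30))
TRBJ_GENES = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 4, 5, 6))

# fixed per-stage offsets fanned out from the global seed
_STAGE = {"repertoire": 11, "tissue": 23, "cells": 37, "transcripts": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], int(seed)])


class GenerationError(RuntimeError):
    """Raised when a geometry cannot be realised within bounded retries."""


@dataclass
class GroundTruthManifest:
    """Everything needed to score recovery of the simulated parameters."""

    seed: int
    repertoire: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# repertoire pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepertoireSimParams:
    """Parameters for a two-sample clonotype-table simulation.

    Forced frequencies pin designated clones to known expected frequencies:
    ``top_clone_freqs_a/b`` apply to the first shared clones (aligned, so
    the i-th entry of both lists refers to the same clone; ``None`` leaves
    that clone tail-weighted in that sample), ``unique_top_freqs_a/b`` to
    the first sample-unique clones. All remaining clones draw their size
    from a discrete power law with exponent ``tail_exponent`` and are
    normalised jointly with the forced frequencies; an optional
    ``tail_max_freq`` cap clips tail clones so none can rival the forced
    top clones.
    """

    n_clones_a: int
    n_clones_b: int
    shared_clones: int
    top_clone_freqs_a: tuple[float | None, ...] = ()
    top_clone_freqs_b: tuple[float | None, ...] = ()
    unique_top_freqs_a: tuple[float, ...] = ()
    unique_top_freqs_b: tuple[float, ...] = ()
    tail_exponent: float = 2.0
    tail_max_freq: float | None = None
    total_reads_per_sample: int = 100_000
    sample_id_a: str = "biopsy"
    sample_id_b: str = "explant"
    #: CDR3s (e.g. from a specificity reference) written onto the first shared clones
    injected_cdr3_aa: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_clones_a, self.n_clones_b) < 1:
            raise ValueError("clone counts must be positive")
        if not 0 <= self.shared_clones <= min(self.n_clones_a, self.n_clones_b):
            raise ValueError("shared_clones must be <= min(n_clones_a, n_clones_b)")
        for name, forced in (("a", self._forced_a()), ("b", self._forced_b())):
            vals = [f for f in forced if f is not None]
            if any(not 0 < f < 1 for f in vals):
                raise ValueError(f"forced frequencies for sample {name} must be in (0,1)")
            if sum(vals) >= 1:
                raise ValueError(f"forced frequencies for sample {name} sum to >= 1")
        if len(self.top_clone_freqs_a) > self.shared_clones or \
           len(self.top_clone_freqs_b) > self.shared_clones:
            raise ValueError("more forced shared frequencies than shared clones")
        if len(self.unique_top_freqs_a) > self.n_clones_a - self.shared_clones:
            raise ValueError("more forced unique frequencies than unique clones in a")
        if len(self.unique_top_freqs_b) > self.n_clones_b - self.shared_clones:
            raise ValueError("more forced unique frequencies than unique clones in b")
        if self.tail_exponent <= 1:
            raise ValueError("tail_exponent must be > 1")
        if self.total_reads_per_sample < 1:
            raise ValueError("total_reads_per_sample must be positive")
        if len(self.injected_cdr3_aa) > self.shared_clones:
            raise ValueError("more injected CDR3s than shared clones")

    def _forced_a(self):
        return tuple(self.top_clone_freqs_a) + tuple(self.unique_top_freqs_a)

    def _forced_b(self):
        return tuple(self.top_clone_freqs_b) + tuple(self.unique_top_freqs_b)


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    middle = "".join(rng.choice(list(AA20), size=length - 2))
    return "C" + middle + "F"


def back_translate(aa: str) -> str:
    """Deterministic codon back-translation of an amino-acid sequence."""
    return "".join(_CODONS[c] for c in aa)


def _tail_frequencies(rng, n_tail: int, tail_mass: float,
                      exponent: float, max_freq: float | None) -> np.ndarray:
    """Power-law tail sizes normalised to tail_mass, each capped at max_freq."""
    if n_tail == 0:
        return np.zeros(0)
    sizes = rng.zipf(exponent, size=n_tail).astype(float)
    if max_freq is not None:
        if max_freq * n_tail < tail_mass - 1e-12:
            raise ValueError("tail_max_freq too small to carry the residual mass")
        for _ in range(200):  # iterative clipping; converges in a few rounds
            total = sizes.sum()
            cap = max_freq * total / tail_mass
            clipped = np.minimum(sizes, cap)
            if np.allclose(clipped, sizes):
                break
            sizes = clipped
    return tail_mass * sizes / sizes.sum()


def _sample_counts(rng, freqs: np.ndarray, total_reads: int) -> np.ndarray:
    """Multinomial counts, bumped so every clone keeps at least one read."""
    counts = rng.multinomial(total_reads, freqs)
    zero = counts == 0
    if zero.any():
        counts[zero] = 1
        counts[np.argmax(counts)] -= int(zero.sum())
    return counts


def generate_repertoire_pair(
    params: RepertoireSimParams,
    manifest: GroundTruthManifest | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Simulate two clonotype tables with a known sharing structure.

    Returns AIRR-style tables (sample_id, v_call, j_call, junction_aa,
    junction, duplicate_count) with exactly ``n_clones_a`` / ``n_clones_b``
    distinct clones, the designated shared clones present in both, and read
    counts multinomial given the designed frequency vectors.
    """
    params.validate()
    rng = _rng(params.seed, "repertoire")
    manifest = manifest or GroundTruthManifest(seed=params.seed)

    n_total = params.n_clones_a + params.n_clones_b - params.shared_clones
    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < n_total:
        s = _random_cdr3(rng)
        if s not in seen:
            seen.add(s)
            cdr3s.append(s)
    for i, inj in enumerate(params.injected_cdr3_aa):
        cdr3s[i] = inj
    v_calls = rng.choice(TRBV_GENES, size=n_total)
    j_calls = rng.choice(TRBJ_GENES, size=n_total)

    n_sh = params.shared_clones
    idx_shared = np.arange(n_sh)
    idx_unique_a = np.arange(n_sh, params.n_clones_a)
    idx_unique_b = np.arange(params.n_clones_a, n_total)

    def build_sample(sample_id, idx_all, forced_shared, forced_unique, n_unique_start):
        freqs = np.full(len(idx_all), np.nan)
        for i, f in enumerate(forced_shared):
            if f is not None:
                freqs[i] = f
        for i, f in enumerate(forced_unique):
            freqs[n_unique_start + i] = f
        forced_mass = np.nansum(freqs)
        free = np.isnan(freqs)
        freqs[free] = _tail_frequencies(
            rng, int(free.sum()), 1.0 - forced_mass,
            params.tail_exponent, params.tail_max_freq)
        counts = _sample_counts(rng, freqs, params.total_reads_per_sample)
        table = pd.DataFrame({
            "sample_id": sample_id,
            "v_call": [v_calls[k] for k in idx_all],
            "j_call": [j_calls[k] for k in idx_all],
            "junction_aa": [cdr3s[k] for k in idx_all],
            "junction": [back_translate(cdr3s[k]) for k in idx_all],
            "duplicate_count": counts,
        })
        return table, freqs

    idx_a = np.concatenate([idx_shared, idx_unique_a]).astype(int)
    idx_b = np.concatenate([idx_shared, idx_unique_b]).astype(int)
    table_a, freqs_a = build_sample(params.sample_id_a, idx_a,
                                    params.top_clone_freqs_a,
                                    params.unique_top_freqs_a, n_sh)
    table_b, freqs_b = build_sample(params.sample_id_b, idx_b,
                                    params.top_clone_freqs_b,
                                    params.unique_top_freqs_b, n_sh)

    def key(k):
        return f"{v_calls[k]}|{cdr3s[k]}"

    manifest.repertoire = {
        "params": {k: v for k, v in asdict(params).items()},
        "shared_clone_keys": [key(k) for k in idx_shared],
        "true_freqs_a": {key(k): float(f) for k, f in zip(idx_a, freqs_a)},
        "true_freqs_b": {key(k): float(f) for k, f in zip(idx_b, freqs_b)},
    }
    return table_a, table_b, manifest


def svali_like_repertoire_params(seed: int = 0) -> RepertoireSimParams:
    """A repertoire scenario shaped like the study's biopsy/explant pair.

    189 biopsy clones (12 hyperexpanded, top 16%), 508 explant clones
    (9 hyperexpanded, top 14.5%), 59 shared; 10 of the 12 biopsy
    hyperexpanded clones present in the explant, 3 hyperexpanded in both.
    """
    return RepertoireSimParams(
        n_clones_a=189, n_clones_b=508, shared_clones=59,
        # first 10 shared clones hyperexpanded in the biopsy ...
        top_clone_freqs_a=(0.16, 0.05, 0.04, 0.031, 0.026, 0.022,
                           0.019, 0.016, 0.014, 0.012),
        # ... of which only the first 3 stay hyperexpanded in the explant
        top_clone_freqs_b=(0.145, 0.053, 0.052, None, None, None,
                           None, None, None, None),
        unique_top_freqs_a=(0.030, 0.020),
        unique_top_freqs_b=(0.041, 0.032, 0.025, 0.019, 0.014, 0.011),
        tail_exponent=2.0,
        tail_max_freq=0.009,
        total_reads_per_sample=1_000_000,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tissue geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueSimParams:
    """Lobule/portal-tract geometry parameters (all lengths in micrometres).

    Defaults approximate a human liver section: portal tracts ~100 um in
    radius spaced under a millimetre apart, sinusoid lumina occupying on
    the order of a tenth of the lobule, small bile ducts inside each tract.
    """

    width_um: float = 3000.0
    height_um: float = 3000.0
    pixel_size_um: float = 2.0
    n_portal_tracts: int = 5
    portal_radius_um: float = 110.0
    portal_radius_jitter: float = 0.15
    sinusoid_fraction: float = 0.10
    sinusoid_width_um: float = 8.0
    duct_radius_um: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_um, self.height_um, self.pixel_size_um) <= 0:
            raise ValueError("dimensions and pixel size must be positive")
        if self.n_portal_tracts < 0:
            raise ValueError("n_portal_tracts must be >= 0")
        if self.n_portal_tracts and min(self.width_um, self.height_um) < 8 * self.portal_radius_um:
            raise ValueError("raster must span at least 4x the portal diameter")
        if not 0 <= self.sinusoid_fraction < 1:
            raise ValueError("sinusoid_fraction must be in [0,1)")


def _disk_mask(shape, cy, cx, radius_px) -> np.ndarray:
    rr, cc = skdraw.disk((cy, cx), radius_px, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def generate_tissue(params: TissueSimParams) -> tuple[MaskBundle, GroundTruthManifest]:
    """Simulate hepatocyte/portal/sinusoid/duct masks.

    Portal tracts are non-overlapping disks (radius jittered per tract);
    each carries one bile-duct disk. Sinusoids are random-walk polylines
    dilated to ``sinusoid_width_um``, added until they occupy
    ``sinusoid_fraction`` of the lobule. All geometry is sampled in
    physical (um) coordinates, so the same seed yields the same geometry
    at any raster resolution.
    """
    params.validate()
    rng = _rng(params.seed, "tissue")
    px = params.pixel_size_um
    shape = (int(round(params.height_um / px)), int(round(params.width_um / px)))

    # --- portal tracts: rejection-sample non-overlapping centres in um ----
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(params.n_portal_tracts):
        r = params.portal_radius_um * (
            1 + params.portal_radius_jitter * float(rng.uniform(-1, 1)))
        placed = False
        for _attempt in range(2000):
            cx = float(rng.uniform(1.2 * r, params.width_um - 1.2 * r))
            cy = float(rng.uniform(1.2 * r, params.height_um - 1.2 * r))
            if all(np.hypot(cx - ox, cy - oy) > (r + orr) * 1.3
                   for (ox, oy), orr in zip(centres, radii)):
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place portal tract {len(centres) + 1} without overlap")
        centres.append((cx, cy))
        radii.append(r)

    portal = np.zeros(shape, dtype=bool)
    duct = np.zeros(shape, dtype=bool)
    duct_offsets = []
    for (cx, cy), r in zip(centres, radii):
        portal |= _disk_mask(shape, cy / px, cx / px, r / px)
        theta = float(rng.uniform(0, 2 * np.pi))
        dx, dy = 0.4 * r * np.cos(theta), 0.4 * r * np.sin(theta)
        duct_offsets.append((dx, dy))
        duct |= _disk_mask(shape, (cy + dy) / px, (cx + dx) / px,
                           params.duct_radius_um / px)
    duct &= portal  # ducts live inside portal tracts

    lobule = ~portal  # hepatocyte region = tissue minus portal tracts

    # --- sinusoids: dilated random walks confined to the lobule -----------
    sinusoid = np.zeros(shape, dtype=bool)
    n_lobule = int(lobule.sum())
    target = params.sinusoid_fraction * n_lobule
    if target > 0:
        selem = morphology.disk(max(1, int(round(params.sinusoid_width_um / 2 / px))))
        step_um = 40.0
        n_steps = 12
        for _walk in range(5000):
            if sinusoid.sum() >= target:
                break
            x = float(rng.uniform(0, params.width_um))
            y = float(rng.uniform(0, params.height_um))
            heading = float(rng.uniform(0, 2 * np.pi))
            path = np.zeros(shape, dtype=bool)
            for _ in range(n_steps):
                heading += float(rng.normal(0, 0.6))
                nx = np.clip(x + step_um * np.cos(heading), 0, params.width_um - px)
                ny = np.clip(y + step_um * np.sin(heading), 0, params.height_um - px)
                rr, cc = skdraw.line(int(y / px), int(x / px), int(ny / px), int(nx / px))
                path[np.clip(rr, 0, shape[0] - 1), np.clip(cc, 0, shape[1] - 1)] = True
                x, y = float(nx), float(ny)
            sinusoid |= morphology.dilation(path, selem)
        sinusoid &= lobule & ~duct

    hepatocyte = lobule & ~sinusoid
    masks = MaskBundle(hepatocyte=hepatocyte, portal=portal,
                       sinusoid=sinusoid, duct=duct, pixel_size_um=px)
    manifest = GroundTruthManifest(seed=params.seed)
    manifest.tissue = {
        "params": asdict(params),
        "portal_centres_um": centres,
        "portal_radii_um": radii,
        "realised_sinusoid_fraction": float(sinusoid.sum() / max(n_lobule, 1)),
    }
    return masks, manifest


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSimParams:
    """Zone-wise homogeneous Poisson cell placement.

    ``base_density_per_mm2`` gives the density of each cell type across all
    tissue zones. The CD8 pool is split into clone-labelled subpopulations
    (density = CD8 density x ``clone_freq_in_cd8``) and an unlabelled rest;
    labelled densities are multiplied by ``pi_enrichment_factor`` inside the
    portal-interface zone. ``marker_positive_prob`` maps marker ->
    {group: probability}, where a group is a clone label, ``"clone+"``,
    a cell type, or ``"default"`` (first match wins).
    """

    base_density_per_mm2: Mapping[str, float]
    clone_labels: tuple[str, ...] = ("clone1", "clone2", "clone3")
    clone_freq_in_cd8: Mapping[str, float] = None
    cd8_type: str = "CD8_T"
    pi_enrichment_factor: float = 1.0
    marker_positive_prob: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if any(d < 0 for d in self.base_density_per_mm2.values()):
            raise ValueError("densities must be non-negative")
        if self.pi_enrichment_factor < 1:
            raise ValueError("pi_enrichment_factor must be >= 1")
        freqs = self.clone_freq_in_cd8 or {}
        if any(not 0 <= f <= 1 for f in freqs.values()) or sum(freqs.values()) > 1:
            raise ValueError("clone frequencies must be probabilities summing to <= 1")
        for marker, groups in self.marker_positive_prob.items():
            if any(not 0 <= p <= 1 for p in groups.values()):
                raise ValueError(f"marker {marker} has probabilities outside [0,1]")


def _marker_prob(params: CellSimParams, marker: str, cell_type: str,
                 clone: str | None) -> float:
    groups = params.marker_positive_prob.get(marker, {})
    if clone is not None:
        if clone in groups:
            return groups[clone]
        if "clone+" in groups:
            return groups["clone+"]
    if cell_type in groups:
        return groups[cell_type]
    return groups.get("default", 0.0)


def generate_cells(
    zone_map: ZoneMap,
    params: CellSimParams,
    manifest: GroundTruthManifest | None = None,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Place cells by a homogeneous Poisson process per zone and stratum.

    Each cell records its true zone and true clone label. Returns a table
    with columns cell_id, x_um, y_um, cell_type, true_zone, true_clone and
    one boolean ``marker_<name>`` column per configured marker.
    """
    params.validate()
    rng = _rng(params.seed, "cells")
    manifest = manifest or GroundTruthManifest(seed=params.seed)
    px = zone_map.pixel_size_um
    clone_freqs = dict(params.clone_freq_in_cd8 or {})

    zone_pixels = {}
    for z in TISSUE_ZONES:
        yy, xx = np.nonzero(zone_map.labels == int(z))
        zone_pixels[z] = (yy, xx)
    if not any(len(v[0]) for v in zone_pixels.values()):
        raise ValueError("zone map has no tissue zones")

    # strata: (cell_type, clone_label, base density)
    strata: list[tuple[str, str | None, float]] = []
    for ctype, dens in params.base_density_per_mm2.items():
        if ctype == params.cd8_type and clone_freqs:
            for clone, f in clone_freqs.items():
                strata.append((ctype, clone, dens * f))
            strata.append((ctype, None, dens * (1 - sum(clone_freqs.values()))))
        else:
            strata.append((ctype, None, dens))

    rows = []
    for z in TISSUE_ZONES:
        yy, xx = zone_pixels[z]
        area = len(yy) * px**2 * 1e-6
        if area == 0:
            continue
        for ctype, clone, dens in strata:
            lam = dens * area
            if clone is not None and z == Zone.PORTAL_INTERFACE:
                lam *= params.pi_enrichment_factor
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            pick = rng.integers(0, len(yy), size=n)
            x_um = (xx[pick] + rng.uniform(0, 1, size=n)) * px
            y_um = (yy[pick] + rng.uniform(0, 1, size=n)) * px
            for xi, yi in zip(x_um, y_um):
                rows.append((float(xi), float(yi), ctype, z.name, clone))

    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "cell_type",
                                        "true_zone", "true_clone"])
    cells = cells.sample(frac=1.0, random_state=int(rng.integers(2**31))
                         ).reset_index(drop=True)
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(cells))])

    markers = sorted(params.marker_positive_prob)
    for marker in markers:
        probs = np.array([
            _marker_prob(params, marker, ct, cl if isinstance(cl, str) else None)
            for ct, cl in zip(cells["cell_type"], cells["true_clone"])
        ])
        cells[f"marker_{marker}"] = rng.uniform(0, 1, size=len(cells)) < probs

    manifest.cells = {
        "params": {
            "base_density_per_mm2": dict(params.base_density_per_mm2),
            "clone_labels": list(params.clone_labels),
            "clone_freq_in_cd8": clone_freqs,
            "cd8_type": params.cd8_type,
            "pi_enrichment_factor": params.pi_enrichment_factor,
            "seed": params.seed,
        },
        "n_cells": int(len(cells)),
        "n_per_zone": cells.groupby("true_zone").size().to_dict(),
    }
    return cells, manifest


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptSimParams:
    """Per-cell Poisson transcript counts with nearest-neighbour bleed-through.

    ``mean_counts`` maps feature -> {group: Poisson rate}; for a clone probe
    the special group ``"self"`` applies to cells whose true clone equals
    the probe name. For other features the group is resolved as the cell's
    clone label, then its cell type, then ``"default"`` (rate 0 when
    absent), so clone-positive cells can carry shifted expression
    programmes with known fold changes. A ``bleedthrough_rate`` fraction of transcripts is reassigned
    to the nearest *other* cell while keeping its (jittered) position.
    Quality values are uniform on [20, 40], above the default quality
    cutoff, so recovery tests see every simulated transcript.
    """

    panel: tuple[str, ...]
    mean_counts: Mapping[str, Mapping[str, float]]
    clone_probe_names: tuple[str, ...] = ()
    bleedthrough_rate: float = 0.0
    position_jitter_sigma_um: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.bleedthrough_rate < 1:
            raise ValueError("bleedthrough_rate must be in [0,1)")
        if self.position_jitter_sigma_um < 0:
            raise ValueError("position_jitter_sigma_um must be >= 0")
        missing = [p for p in self.clone_probe_names if p not in self.panel]
        if missing:
            raise ValueError(f"clone probes missing from panel: {missing}")
        unknown = [f for f in self.mean_counts if f not in self.panel]
        if unknown:
            raise ValueError(f"rate table features not in panel: {unknown}")
        for f, groups in self.mean_counts.items():
            if any(r < 0 for r in groups.values()):
                raise ValueError(f"negative rate for feature {f}")


def _rate(params: TranscriptSimParams, feature: str, cell_type: str,
          clone: str | None) -> float:
    groups = params.mean_counts.get(feature, {})
    if feature in params.clone_probe_names:
        return groups.get("self", 0.0) if clone == feature else groups.get("default", 0.0)
    if clone is not None and clone in groups:
        return groups[clone]
    if cell_type in groups:
        return groups[cell_type]
    return groups.get("default", 0.0)


def generate_transcripts(
    cells: pd.DataFrame,
    params: TranscriptSimParams,
    manifest: GroundTruthManifest | None = None,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Simulate a transcript table for the given cells.

    Returns columns transcript_id, feature_name, x_um, y_um, cell_id, qv,
    plus the ground-truth ``source_cell_id`` (equal to cell_id unless the
    transcript bled through to a neighbour).
    """
    params.validate()
    if len(cells) == 0:
        raise ValueError("cells table is empty")
    rng = _rng(params.seed, "transcripts")
    manifest = manifest or GroundTruthManifest(seed=params.seed)

    ctypes = cells["cell_type"].to_numpy()
    clones = cells["true_clone"].to_numpy() if "true_clone" in cells.columns \
        else np.full(len(cells), None)
    xs, ys = cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)
    ids = cells["cell_id"].to_numpy()

    feat_col, src_idx = [], []
    for feature in params.panel:
        rates = np.array([
            _rate(params, feature, ct, cl if isinstance(cl, str) else None)
            for ct, cl in zip(ctypes, clones)
        ])
        counts = rng.poisson(rates)
        nz = np.nonzero(counts)[0]
        rep = np.repeat(nz, counts[nz])
        src_idx.append(rep)
        feat_col.extend([feature] * len(rep))
    src_idx = np.concatenate(src_idx) if src_idx else np.zeros(0, dtype=int)
    n_tx = len(src_idx)

    x = xs[src_idx] + rng.normal(0, params.position_jitter_sigma_um, size=n_tx)
    y = ys[src_idx] + rng.normal(0, params.position_jitter_sigma_um, size=n_tx)
    assigned = src_idx.copy()

    n_bled = 0
    if params.bleedthrough_rate > 0 and len(cells) > 1:
        bleed = rng.uniform(0, 1, size=n_tx) < params.bleedthrough_rate
        n_bled = int(bleed.sum())
        if n_bled:
            tree = cKDTree(np.column_stack([xs, ys]))
            _, nn = tree.query(np.column_stack([xs, ys]), k=2)
            nearest_other = nn[:, 1]
            assigned[bleed] = nearest_other[src_idx[bleed]]

    tx = pd.DataFrame({
        "transcript_id": [f"t{i:07d}" for i in range(n_tx)],
        "feature_name": feat_col,
        "x_um": x,
        "y_um": y,
        "cell_id": ids[assigned],
        "qv": rng.uniform(20, 40, size=n_tx),
        "source_cell_id": ids[src_idx],
    })
    tx = tx.sample(frac=1.0, random_state=int(rng.integers(2**31))
                   ).reset_index(drop=True)
    manifest.transcripts = {
        "params": {
            "panel": list(params.panel),
            "clone_probe_names": list(params.clone_probe_names),
            "bleedthrough_rate": params.bleedthrough_rate,
            "position_jitter_sigma_um": params.position_jitter_sigma_um,
            "seed": params.seed,
        },
        "n_transcripts": int(n_tx),
        "n_bled": n_bled,
        "realised_bleed_fraction": float(n_bled / n_tx) if n_tx else 0.0,
    }
    return tx, manifest
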