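"""Ground-truthed synthetic LC-MS peptide tables and IMS datasets.

The generator emulates a two-condition ("control" vs "case", e.g. wild-type
vs transgenic testis) experiment:

* a shotgun LC-MS peptide evidence table in the MaxQuant ``peptides.txt``
  dialect — two groups x 3 replicates, log-normal base abundances, planted
  per-protein log2 fold changes (point masses at 0 and at +/- a planted
  effect), and missing-not-at-random low-abundance values driven by a
  logistic detection-limit model;
* a MALDI-IMS dataset on a pixel grid partitioned into 2-5 spatial regions
  (tubular vs interstitial analogues), where a subset of the LC-MS peptides
  is rendered as singly charged averagine isotope envelopes with
  multiplicative intensity noise, per-pixel gain variation, additive
  baseline noise peaks, and centroid mass error ~ Normal(0, mass_error_sd);
* near-isobaric decoy peptides in the LC-MS table (within the tau-search
  window of each imaged peptide but at lower abundance), exercising the
  ambiguity the MLP score resolves.

Every planted value is recorded in a :class:`GroundTruth` object so each
downstream stage can be scored against what was actually simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ims import IMSDataset
from .isotopes import ISOTOPE_SPACING, PROTON_MASS, averagine_envelope, envelope_ratios

logger = logging.getLogger(__name__)

_RESIDUES = "ACDEFGHIKLMNPQSTVWY"  # amino acids for decorative tryptic sequences


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic two-condition experiment.

    The defaults describe the emulated study: 3 replicates per group,
    600-3200 Da mass range, a 64x64 pixel grid with 3 spatial regions,
    4-peak isotope envelopes and a centroid mass error SD of 0.04 Da (so
    ~2.5 sigma falls within the +/-0.1 Da accuracy envelope).
    """

    n_proteins: int = 700
    peptides_per_protein: tuple[int, int] = (2, 5)
    n_replicates_per_group: int = 3
    # fold-change distribution: per protein, log2FC is 0 with probability
    # (1 - fraction_differential) and +/- planted_log2fc otherwise.  Most of
    # a proteome is unchanged between conditions; the imaged, region-confined
    # peptides are drawn from the differential minority.
    planted_log2fc: float = 3.0
    fraction_differential: float = 0.2
    # missingness: logistic in log2 intensity around a detection-limit quantile
    missing_quantile: float = 0.10
    missing_steepness: float = 1.5
    # intensity model (log2 scale)
    log2_abundance_mean: float = 25.0
    log2_abundance_sd: float = 2.0
    replicate_sd: float = 0.5
    # IMS geometry and rendering
    grid_shape: tuple[int, int] = (64, 64)
    n_regions: int = 3
    mass_range: tuple[float, float] = (600.0, 3200.0)
    mass_error_sd: float = 0.04
    isotope_peaks: int = 4
    n_ims_peptides: int = 300
    n_decoys_per_ims_peptide: int = 3
    ims_base_intensity: float = 1000.0
    ims_abundance_log2_sd: float = 1.0
    ims_gain_sigma: float = 0.3  # log-normal per-pixel gain (exercises TIC normalization)
    # log-normal per-pixel abundance texture of each peptide, shared by all
    # of its isotope peaks — the spatial signal co-localization relies on
    ims_texture_sigma: float = 0.5
    ims_mult_sigma: float = 0.15  # log-normal per-peak detection noise, independent per peak
    noise_peaks_per_pixel: int = 5
    noise_intensity: float = 20.0
    spatial_resolution_um: float = 25.0
    group_names: tuple[str, str] = ("control", "case")
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.mass_range[0] < self.mass_range[1]):
            raise ConfigError(f"mass_range: must satisfy 0 < low < high, got {self.mass_range}")
        if self.n_replicates_per_group < 2:
            raise ConfigError(f"n_replicates_per_group: must be >= 2, got {self.n_replicates_per_group}")
        if self.grid_shape[0] < 8 or self.grid_shape[1] < 8:
            raise ConfigError(f"grid_shape: grid must be at least 8x8, got {self.grid_shape}")
        if not (2 <= self.n_regions <= 5):
            raise ConfigError(f"n_regions: must be in [2, 5], got {self.n_regions}")
        if self.peptides_per_protein[0] < 1 or self.peptides_per_protein[0] > self.peptides_per_protein[1]:
            raise ConfigError(f"peptides_per_protein: invalid range {self.peptides_per_protein}")
        if self.isotope_peaks < 1:
            raise ConfigError(f"isotope_peaks: must be >= 1, got {self.isotope_peaks}")
        if not (0 <= self.missing_quantile < 1):
            raise ConfigError(f"missing_quantile: must be in [0, 1), got {self.missing_quantile}")
        if self.mass_error_sd < 0:
            raise ConfigError(f"mass_error_sd: must be >= 0, got {self.mass_error_sd}")
        if self.n_ims_peptides < 0:
            raise ConfigError(f"n_ims_peptides: must be >= 0, got {self.n_ims_peptides}")


@dataclass
class GroundTruth:
    """Everything that was planted, for scoring the pipeline against.

    ``peptides`` has one row per LC-MS peptide (decoys included) with the
    planted protein, neutral monoisotopic mass, log2 fold change, log2 base
    abundance, and — for peptides rendered in the IMS dataset — the region
    index and IMS abundance (``ims_region`` is -1 for unimaged peptides).
    """

    peptides: pd.DataFrame
    region_map: np.ndarray  # (n_rows, n_cols) int region labels
    region_condition: dict[int, str]
    config: SimConfig
    skipped_peptides: list[str] = field(default_factory=list)

    def imaged(self) -> pd.DataFrame:
        return self.peptides[self.peptides["ims_region"] >= 0]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.peptides.to_csv(directory / "truth_peptides.tsv", sep="\t", index=False)
        np.savetxt(directory / "truth_region_map.txt", self.region_map, fmt="%d")
        with open(directory / "truth_region_condition.tsv", "w") as fh:
            fh.write("region\tcondition\n")
            for r, c in sorted(self.region_condition.items()):
                fh.write(f"{r}\t{c}\n")


def _random_sequence(rng: np.random.Generator, mass: float) -> str:
    """A decorative tryptic-like sequence (ends in K/R) of plausible length."""
    n = max(int(round(mass / 111.0)), 2)
    body = "".join(rng.choice(list(_RESIDUES), size=n - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def _voronoi_regions(grid_shape: tuple[int, int], n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into contiguous regions via nearest seed point."""
    rows, cols = grid_shape
    seeds = np.column_stack([rng.uniform(0, rows, n_regions), rng.uniform(0, cols, n_regions)])
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1).reshape(rows, cols)
    # guarantee no region is empty (resample seeds until all present)
    while len(np.unique(labels)) < n_regions:
        seeds = np.column_stack([rng.uniform(0, rows, n_regions), rng.uniform(0, cols, n_regions)])
        d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1).reshape(rows, cols)
    return labels


def generate_lcms_table(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the MaxQuant-style peptide evidence table and its ground truth.

    Returns the table (columns ``Sequence, Mass, Proteins, Leading razor
    protein, Unique, Intensity <group>_<rep>...``; missing intensities are
    written as 0, the MaxQuant convention) and the :class:`GroundTruth`
    recording all planted values, including the spatial region layout used
    later by :func:`generate_ims_dataset`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    lo, hi = config.mass_range
    envelope_extent = (config.isotope_peaks - 1) * ISOTOPE_SPACING

    # --- proteins and their planted fold changes -------------------------
    rows = []
    for p in range(config.n_proteins):
        protein = f"P{p:04d}"
        if rng.random() < config.fraction_differential:
            fc = config.planted_log2fc * (1.0 if rng.random() < 0.5 else -1.0)
        else:
            fc = 0.0
        n_pep = int(rng.integers(config.peptides_per_protein[0], config.peptides_per_protein[1] + 1))
        for _ in range(n_pep):
            mass = float(rng.uniform(lo + 5.0, hi - envelope_extent - 5.0))
            rows.append(
                dict(
                    sequence=_random_sequence(rng, mass),
                    protein=protein,
                    mass=mass,
                    log2fc=fc,
                    base_log2=float(rng.normal(config.log2_abundance_mean, config.log2_abundance_sd)),
                    unique=bool(rng.random() < 0.9),
                    is_decoy=False,
                )
            )
    pep = pd.DataFrame(rows)
    pep["ims_region"] = -1
    pep["ims_abundance"] = 0.0

    # --- spatial layout and IMS peptide selection ------------------------
    region_map = _voronoi_regions(config.grid_shape, config.n_regions, rng)
    region_condition = {
        r: config.group_names[1] if r % 2 == 0 else config.group_names[0]
        for r in range(config.n_regions)
    }
    case_regions = [r for r, c in region_condition.items() if c == config.group_names[1]]
    ctrl_regions = [r for r, c in region_condition.items() if c == config.group_names[0]]

    # Peptides imaged by MALDI are drawn from the differential peptides whose
    # planted direction matches their region's condition (the search-space
    # assumption), with an abundance boost reflecting that MALDI-TOF
    # preferentially detects relatively abundant peptides.
    up = pep.index[pep["log2fc"] > 0].to_numpy()
    dn = pep.index[pep["log2fc"] < 0].to_numpy()
    rng.shuffle(up)
    rng.shuffle(dn)
    per_region = np.full(config.n_regions, config.n_ims_peptides // config.n_regions)
    per_region[: config.n_ims_peptides % config.n_regions] += 1
    pools = {True: list(up), False: list(dn)}
    for r in range(config.n_regions):
        is_case = r in case_regions
        take = min(per_region[r], len(pools[is_case]))
        if take < per_region[r]:
            logger.warning("region %d: only %d candidate peptides for %d slots", r, take, per_region[r])
        chosen = [pools[is_case].pop() for _ in range(take)]
        pep.loc[chosen, "ims_region"] = r
        pep.loc[chosen, "base_log2"] += 2.0
        pep.loc[chosen, "ims_abundance"] = config.ims_base_intensity * np.exp2(
            rng.normal(0.0, config.ims_abundance_log2_sd, size=take)
        )

    # --- near-isobaric decoys -------------------------------------------
    decoy_rows = []
    imaged_idx = pep.index[pep["ims_region"] >= 0]
    for j, i in enumerate(imaged_idx):
        for d in range(config.n_decoys_per_ims_peptide):
            offset = float(rng.uniform(-0.07, 0.07))
            if rng.random() < config.fraction_differential:
                fc = config.planted_log2fc * (1.0 if rng.random() < 0.5 else -1.0)
            else:
                fc = 0.0
            mass = float(pep.at[i, "mass"]) + offset
            # decoys sit at least ~8x below their target's abundance: the
            # ambiguity the MLP score resolves is between an abundant,
            # confidently differential peptide and near-isobaric peptides of
            # lower planted mu * |log2FC|
            decoy_rows.append(
                dict(
                    sequence=_random_sequence(rng, mass),
                    protein=f"D{j:04d}_{d}",
                    mass=mass,
                    log2fc=fc,
                    base_log2=float(pep.at[i, "base_log2"] - 3.0 - abs(rng.normal(0.0, 1.0))),
                    unique=True,
                    is_decoy=True,
                    ims_region=-1,
                    ims_abundance=0.0,
                )
            )
    if decoy_rows:
        pep = pd.concat([pep, pd.DataFrame(decoy_rows)], ignore_index=True)

    # --- replicate intensities and MNAR missingness ----------------------
    n_rep = config.n_replicates_per_group
    g0, g1 = config.group_names
    log2_int = np.empty((len(pep), 2 * n_rep))
    half_fc = pep["log2fc"].to_numpy() / 2.0
    base = pep["base_log2"].to_numpy()
    for r in range(n_rep):
        log2_int[:, r] = base - half_fc + rng.normal(0, config.replicate_sd, len(pep))
        log2_int[:, n_rep + r] = base + half_fc + rng.normal(0, config.replicate_sd, len(pep))
    if config.missing_quantile > 0:
        thr = np.quantile(log2_int, config.missing_quantile)
        p_missing = 1.0 / (1.0 + np.exp((log2_int - thr) / config.missing_steepness))
        missing = rng.random(log2_int.shape) < p_missing
    else:
        missing = np.zeros(log2_int.shape, dtype=bool)
    linear = np.exp2(log2_int)
    linear[missing] = 0.0

    table = pd.DataFrame(
        {
            "Sequence": pep["sequence"],
            "Mass": pep["mass"],
            "Proteins": pep["protein"],
            "Leading razor protein": pep["protein"],
            "Unique": np.where(pep["unique"], "yes", "no"),
        }
    )
    for r in range(n_rep):
        table[f"Intensity {g0}_{r + 1}"] = linear[:, r]
    for r in range(n_rep):
        table[f"Intensity {g1}_{r + 1}"] = linear[:, n_rep + r]

    truth = GroundTruth(pep, region_map, region_condition, config)
    return table, truth


def generate_ims_dataset(config: SimConfig, truth: GroundTruth) -> IMSDataset:
    """Render the imaged peptides of ``truth`` onto the pixel grid.

    Each imaged peptide appears in every pixel of its region as a full
    singly protonated isotope envelope: peak k at
    ``(neutral mass + 1.007276) + k * 1.00235`` Da plus a centroid
    error ~ Normal(0, mass_error_sd) drawn per pixel and per peak, with
    intensity ``ims_abundance * averagine_ratio_k`` scaled by (i) the
    peptide's log-normal spatial abundance texture, drawn per pixel and
    shared by all isotope peaks of that peptide, (ii) independent log-normal
    per-peak detection noise, and (iii) a log-normal per-pixel gain common
    to all peaks of a pixel.  Uniform-m/z baseline noise
    peaks of low intensity are added to every pixel.  Peptides whose
    envelope would extend outside the mass range are skipped with a logged
    warning.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    lo, hi = config.mass_range
    rows, cols = config.grid_shape
    region_map = truth.region_map
    n_pixels = rows * cols
    coords = np.stack(
        [np.tile(np.arange(cols), rows), np.repeat(np.arange(rows), cols)], axis=1
    )  # (x=col, y=row), row-major order
    pixel_region = region_map[coords[:, 1], coords[:, 0]]
    gain = (
        np.exp(rng.normal(0.0, config.ims_gain_sigma, n_pixels))
        if config.ims_gain_sigma > 0
        else np.ones(n_pixels)
    )

    imaged = truth.imaged()
    extent = (config.isotope_peaks - 1) * ISOTOPE_SPACING
    keep = (imaged["mass"] + PROTON_MASS >= lo) & (
        imaged["mass"] + PROTON_MASS + extent <= hi + 0.3
    )
    for seq in imaged.loc[~keep, "sequence"]:
        logger.warning("peptide %s: envelope outside mass range, skipped", seq)
        truth.skipped_peptides.append(seq)
    imaged = imaged.loc[keep]

    mz_per_pixel: list[list[np.ndarray]] = [[] for _ in range(n_pixels)]
    int_per_pixel: list[list[np.ndarray]] = [[] for _ in range(n_pixels)]

    for r in range(config.n_regions):
        sel = imaged[imaged["ims_region"] == r]
        pix = np.flatnonzero(pixel_region == r)
        if not len(sel) or not len(pix):
            continue
        mono = sel["mass"].to_numpy() + PROTON_MASS  # MALDI observes singly protonated MH+
        abund = sel["ims_abundance"].to_numpy()
        ratios = np.stack([envelope_ratios(m, config.isotope_peaks) for m in mono])
        centers = mono[:, None] + np.arange(config.isotope_peaks)[None, :] * ISOTOPE_SPACING
        base_int = abund[:, None] * ratios  # (n_pep, n_iso)
        n_peaks = centers.size
        flat_centers = centers.ravel()
        flat_int = base_int.ravel()
        n_pep = len(sel)
        n_iso = config.isotope_peaks
        for p in pix:
            mz = flat_centers + (
                rng.normal(0.0, config.mass_error_sd, n_peaks) if config.mass_error_sd > 0 else 0.0
            )
            inten = flat_int * gain[p]
            if config.ims_texture_sigma > 0:
                texture = np.exp(rng.normal(0.0, config.ims_texture_sigma, n_pep))
                inten = inten * np.repeat(texture, n_iso)
            if config.ims_mult_sigma > 0:
                inten = inten * np.exp(rng.normal(0.0, config.ims_mult_sigma, n_peaks))
            mz_per_pixel[p].append(mz)
            int_per_pixel[p].append(inten)

    if config.noise_peaks_per_pixel > 0:
        for p in range(n_pixels):
            nm = rng.uniform(lo, hi, config.noise_peaks_per_pixel)
            ni = rng.exponential(config.noise_intensity, config.noise_peaks_per_pixel) * gain[p]
            mz_per_pixel[p].append(nm)
            int_per_pixel[p].append(ni)

    mzs, intens = [], []
    for p in range(n_pixels):
        if mz_per_pixel[p]:
            mz = np.concatenate(mz_per_pixel[p])
            ii = np.concatenate(int_per_pixel[p])
            np.clip(mz, lo - 0.5, hi + 0.5, out=mz)
            order = np.argsort(mz, kind="stable")
            mz, ii = mz[order], ii[order]
            # strictly increasing m/z: merge exact duplicates
            dup = np.flatnonzero(np.diff(mz) == 0)
            if len(dup):
                np.add.at(ii, dup, ii[dup + 1])
                keep_mask = np.ones(len(mz), dtype=bool)
                keep_mask[dup + 1] = False
                mz, ii = mz[keep_mask], ii[keep_mask]
            mzs.append(mz)
            intens.append(ii)
        else:
            mzs.append(np.zeros(0))
            intens.append(np.zeros(0))

    ds = IMSDataset(
        coords,
        mzs,
        intens,
        config.mass_range,
        spatial_resolution_um=config.spatial_resolution_um,
    )
    return ds


def write_peptides_table(table: pd.DataFrame, path) -> None:
    """Write the evidence table as tab-separated text (peptides.txt dialect)."""
    table.to_csv(path, sep="\t", index=False)


__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "generate_lcms_table",
    "generate_ims_dataset",
    "averagine_envelope",
    "write_peptides_table",
]
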