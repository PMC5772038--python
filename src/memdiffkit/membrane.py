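"""Membrane metrics computed from bilayer particle ensembles.

The metrics quantify how amphiphilic solutes (here ethanol and n-butanol)
perturb a lipid bilayer:

* **area per lipid** — lateral box area divided by the lipids per leaflet,
  the standard packing metric;
* **bilayer thickness** — distance between the phosphate density peaks of
  the two leaflets;
* **deuterium order parameter** S_CD(i) = <(3 cos^2 theta - 1)/2> for the
  C-H bond of carbon i against the membrane normal, whose magnitude measures
  acyl-chain order (the inverse of fluidity);
* **interior water** — waters inside the region where the sphingolipid tail
  density exceeds the water density;
* **alcohol partitioning** — fraction of alcohol molecules outside the bulk
  water region (bulk = where water density exceeds phosphate density);
* **insertion depth** — signed distance of an alcohol group's density peak
  from the POPI glycerol-backbone peak, positive toward the bilayer centre.

Uncertainties follow the conventions of the profile module: block averaging
for slowly-relaxing box/order observables, a 100-sample frame bootstrap for
profile intercept and peak derived quantities, all at 95%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import AnalysisError, SelectionError
from .profiles import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_N_BLOCKS,
    DEFAULT_N_BOOT,
    DensityProfile,
    IntervalEstimate,
    _rng,
    _single_crossing,
    block_average,
    block_slices,
    density_profile,
    folded_profile,
    peak_z,
    t_interval_from_blocks,
)

WATER_SEL = {"role": "water_oxygen"}
PHOSPHATE_SEL = {"role": "phosphate"}
IPC_TAIL_SEL = {"species": "IPC", "role": "tail_carbon"}
GLYCEROL_SEL = {"species": "POPI", "role": "glycerol_backbone"}

MOLAR_MASS_G_PER_MOL = {"WATER": 18.02, "ETHANOL": 46.07, "BUTANOL": 74.12}
BULK_DENSITY_G_PER_ML = {"WATER": 0.997, "ETHANOL": 0.789, "BUTANOL": 0.810}


# ---------------------------------------------------------------------------
# Box-derived metrics
# ---------------------------------------------------------------------------


def area_per_lipid(
    ens, lipids_per_leaflet: int, n_blocks: int = DEFAULT_N_BLOCKS
) -> IntervalEstimate:
    """Lateral box area per lipid in one leaflet (nm^2), block averaged.

    The divisor is the lipids *per leaflet*: each leaflet independently tiles
    the lateral box area, so a 128-lipid bilayer with a ~34 nm^2 box has an
    area per lipid of ~0.53 nm^2.
    """
    if lipids_per_leaflet <= 0:
        raise AnalysisError("lipids_per_leaflet must be positive")
    series = ens.boxes[:, 0] * ens.boxes[:, 1] / float(lipids_per_leaflet)
    nb = min(n_blocks, len(series) // 2)
    if nb < 2:
        v = float(series.mean())
        return IntervalEstimate(v, v, v, "block", 1)
    return block_average(series, nb)


# ---------------------------------------------------------------------------
# Thickness
# ---------------------------------------------------------------------------


def _profile_like(profile: DensityProfile, density: np.ndarray) -> DensityProfile:
    return DensityProfile(
        bin_edges=profile.bin_edges,
        density=density,
        selection_label=profile.selection_label,
        n_frames=profile.n_frames,
    )


def _thickness_from_density(profile: DensityProfile, density: np.ndarray) -> float:
    half = float(profile.bin_edges[-1])
    w = profile.bin_width
    p = _profile_like(profile, density)
    z_up = peak_z(p, (w, half))
    z_lo = peak_z(p, (-half, -w))
    return z_up - z_lo


def bilayer_thickness(
    ens,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> IntervalEstimate:
    """Distance between the phosphate density peaks of the two leaflets (nm).

    The point estimate uses the full-ensemble profile; the uncertainty is a
    Student-t interval over per-block peak distances (block averaging).
    """
    profile = density_profile(ens, PHOSPHATE_SEL, bin_width)
    value = _thickness_from_density(profile, profile.density)
    pf = profile.per_frame_density
    blocks = []
    for s in block_slices(pf.shape[0], min(n_blocks, max(1, pf.shape[0] // 2))):
        blocks.append(_thickness_from_density(profile, pf[s].mean(axis=0)))
    return t_interval_from_blocks(value, blocks)


# ---------------------------------------------------------------------------
# Deuterium order parameters
# ---------------------------------------------------------------------------


@dataclass
class ScdResult:
    """Per-carbon signed S_CD and the chain-mean order |S_CD|.

    ``per_carbon`` maps carbon index to a signed block-averaged estimate;
    ``chain_mean`` is the unweighted mean of |S_CD(i)| over the interior
    carbons (the first and last chain carbons are excluded, where the C-H
    geometry reconstruction is undefined).  ``method`` records whether
    explicit tail hydrogens were used or the H direction was reconstructed
    from the C(i-1)->C(i+1) chain axis.
    """

    per_carbon: dict[int, IntervalEstimate]
    chain_mean: IntervalEstimate
    method: str


def _minimum_image(d: np.ndarray, frame_idx: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    # bond/axis vectors must not straddle the periodic boundary
    L = boxes[frame_idx]
    return d - L * np.round(d / L)


def _scd_matrix_from_hydrogens(sub_c, sub_h, n_frames, boxes):
    merged = sub_h.merge(
        sub_c,
        on=["frame", "mol_id", "chain_id", "carbon_index"],
        suffixes=("_h", "_c"),
    )
    if len(merged) == 0:
        return None, None
    d = merged[["x_h", "y_h", "z_h"]].to_numpy() - merged[
        ["x_c", "y_c", "z_c"]
    ].to_numpy()
    d = _minimum_image(d, merged["frame"].to_numpy(), boxes)
    norm = np.linalg.norm(d, axis=1)
    cos = d[:, 2] / norm
    s = 0.5 * (3.0 * cos**2 - 1.0)
    merged = merged.assign(scd=s)
    grouped = merged.groupby(["frame", "carbon_index"])["scd"].mean().unstack()
    carbons = [int(c) for c in grouped.columns]
    mat = np.full((n_frames, len(carbons)), np.nan)
    mat[grouped.index.to_numpy(), :] = grouped.to_numpy()
    return carbons, mat


def _scd_matrix_from_axis(sub_c, n_frames, boxes):
    # Reconstruct the C-H orientation statistics from the chain geometry:
    # with hydrogens uniformly distributed in the plane perpendicular to the
    # local chain axis a = C(i+1) - C(i-1), <S_CH> = -S_aa / 2.
    sub = sub_c.sort_values(["frame", "mol_id", "carbon_index"], kind="stable")
    carbons_all = np.sort(sub["carbon_index"].unique())
    n_c = len(carbons_all)
    per_mol = sub.groupby(["frame", "mol_id"]).size()
    if per_mol.nunique() != 1 or per_mol.iloc[0] != n_c:
        raise AnalysisError(
            "axis-based order parameters require every chain to carry the "
            "same carbon indices"
        )
    xyz = sub[["x", "y", "z"]].to_numpy().reshape(-1, n_c, 3)
    frames = sub["frame"].to_numpy().reshape(-1, n_c)[:, 0]
    axis = xyz[:, 2:, :] - xyz[:, :-2, :]  # chains x (n_c - 2) x 3
    flat = axis.reshape(-1, 3)
    flat = _minimum_image(flat, np.repeat(frames, n_c - 2), boxes)
    axis = flat.reshape(axis.shape)
    norm = np.linalg.norm(axis, axis=2)
    cos = axis[:, :, 2] / norm
    s_axis = 0.5 * (3.0 * cos**2 - 1.0)
    s_ch = -0.5 * s_axis
    carbons = [int(c) for c in carbons_all[1:-1]]
    mat = np.full((n_frames, len(carbons)), np.nan)
    for fi in range(n_frames):
        rows = frames == fi
        if rows.any():
            mat[fi] = s_ch[rows].mean(axis=0)
    return carbons, mat


def deuterium_order_parameters(
    ens,
    species: str = "IPC",
    chain_id: int = 1,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> ScdResult:
    """S_CD per carbon and the chain-mean order for one acyl chain.

    Uses explicit tail hydrogens when the ensemble carries them; otherwise
    falls back to the geometric reconstruction from the chain axis.
    Uncertainties are block-averaging intervals over frames.
    """
    sel_c = {"species": species, "role": "tail_carbon", "chain_id": chain_id}
    sub_c = ens.select(sel_c)
    if len(sub_c) == 0:
        raise SelectionError(f"no tail carbons for species={species} chain={chain_id}")
    if sub_c["carbon_index"].nunique() < 3:
        raise AnalysisError("chain must have at least 3 carbons")
    sub_h = ens.select({"species": species, "role": "tail_hydrogen", "chain_id": chain_id})
    if len(sub_h):
        carbons, mat = _scd_matrix_from_hydrogens(sub_c, sub_h, ens.n_frames, ens.boxes)
        method = "hydrogen"
    else:
        carbons, mat = _scd_matrix_from_axis(sub_c, ens.n_frames, ens.boxes)
        method = "axis_reconstruction"
    nb = min(n_blocks, max(1, mat.shape[0] // 2))
    slices = block_slices(mat.shape[0], nb)
    per_carbon = {}
    full_means = np.nanmean(mat, axis=0)
    block_means = np.array([np.nanmean(mat[s], axis=0) for s in slices])
    for j, ci in enumerate(carbons):
        per_carbon[ci] = t_interval_from_blocks(float(full_means[j]), block_means[:, j])
    interior = [j for j, ci in enumerate(carbons) if ci not in (min(carbons), max(carbons))]
    if method == "axis_reconstruction":
        interior = list(range(len(carbons)))  # edges already excluded
    if not interior:
        interior = list(range(len(carbons)))
    chain_value = float(np.mean(np.abs(full_means[interior])))
    chain_blocks = np.mean(np.abs(block_means[:, interior]), axis=1)
    chain_mean = t_interval_from_blocks(chain_value, chain_blocks)
    return ScdResult(per_carbon=per_carbon, chain_mean=chain_mean, method=method)


# ---------------------------------------------------------------------------
# Interior water
# ---------------------------------------------------------------------------


def _per_frame_sorted_z(ens, sel) -> list[np.ndarray]:
    sub = ens.select(sel)
    frames = sub["frame"].to_numpy()
    z = sub["z"].to_numpy(dtype=float)
    return [np.sort(z[frames == fi]) for fi in range(ens.n_frames)]


def _count_between(sorted_z: np.ndarray, lo: float, hi: float) -> int:
    return int(
        np.searchsorted(sorted_z, hi, side="left")
        - np.searchsorted(sorted_z, lo, side="right")
    )


def interior_water_count(
    ens,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Mean number of waters inside the membrane interior, with bootstrap CI.

    The interior is the z-region where the sphingolipid (IPC) tail-carbon
    density exceeds the water-oxygen density, delimited by the two profile
    intercepts bracketing the midplane.  Waters strictly inside are counted
    per frame and averaged; the bootstrap jointly resamples frames for the
    profiles and the counts.  If either intercept is missing the membrane is
    disrupted and an InterceptError propagates.
    """
    water = density_profile(ens, WATER_SEL, bin_width)
    tail = density_profile(ens, IPC_TAIL_SEL, bin_width)
    half = float(water.bin_edges[-1])
    centers = water.centers
    wz = _per_frame_sorted_z(ens, WATER_SEL)

    def _bounds(diff):
        z_lo = _single_crossing(centers, diff, (-half, 0.0))
        z_hi = _single_crossing(centers, diff, (0.0, half))
        return z_lo, z_hi

    z_lo, z_hi = _bounds(tail.density - water.density)
    value = float(np.mean([_count_between(s, z_lo, z_hi) for s in wz]))
    rng = _rng(seed, rng)
    nf = ens.n_frames
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        diff = tail.per_frame_density[idx].mean(axis=0) - water.per_frame_density[
            idx
        ].mean(axis=0)
        lo, hi = _bounds(diff)
        draws.append(np.mean([_count_between(wz[i], lo, hi) for i in idx]))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


# ---------------------------------------------------------------------------
# Alcohol partitioning and depth
# ---------------------------------------------------------------------------


def _membrane_bounds(water: DensityProfile, phos: DensityProfile, wdens, pdens):
    """Crossings of water and phosphate density outboard of each leaflet peak.

    Bulk water is where the water density exceeds the phosphate density; the
    outermost crossing on each side is found by searching outward from the
    phosphate peak, where the difference water - phosphate rises through
    zero exactly once.
    """
    half = float(water.bin_edges[-1])
    w = water.bin_width
    centers = water.centers
    p = _profile_like(phos, pdens)
    z_pu = peak_z(p, (w, half))
    z_pl = peak_z(p, (-half, -w))
    diff = wdens - pdens
    z_hi = _single_crossing(centers, diff, (z_pu - w, half))
    z_lo = _single_crossing(centers, diff, (-half, z_pl + w))
    return z_lo, z_hi


def partition_fraction(
    ens,
    species: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Percentage of alcohol molecules inside the membrane region.

    The membrane region is the complement of bulk water (bulk = |z| beyond
    the water/phosphate density intercepts).  An alcohol is located by its
    hydroxyl oxygen.  Per-frame fractions are averaged; membrane and bulk
    fractions sum to one per frame by construction.
    """
    sel = {"species": species, "role": "hydroxyl_oxygen"}
    az = _per_frame_sorted_z(ens, sel)
    totals = np.array([len(a) for a in az], dtype=float)
    if totals.sum() == 0:
        raise SelectionError(f"species {species} absent from ensemble")
    if np.any(totals == 0):
        raise AnalysisError(f"species {species} absent from some frames")
    water = density_profile(ens, WATER_SEL, bin_width)
    phos = density_profile(ens, PHOSPHATE_SEL, bin_width)

    def _mean_fraction(idx):
        wdens = water.per_frame_density[idx].mean(axis=0)
        pdens = phos.per_frame_density[idx].mean(axis=0)
        z_lo, z_hi = _membrane_bounds(water, phos, wdens, pdens)
        fracs = [
            _count_between(az[i], z_lo, z_hi) / totals[i] for i in np.atleast_1d(idx)
        ]
        return 100.0 * float(np.mean(fracs))

    all_idx = np.arange(ens.n_frames)
    value = _mean_fraction(all_idx)
    rng = _rng(seed, rng)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = _mean_fraction(rng.integers(0, ens.n_frames, size=ens.n_frames))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


def insertion_depth(
    ens,
    species: str,
    group: str = "terminal_methyl",
    bin_width: float = 0.05,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Depth of an alcohol group's peak below the POPI glycerol peak (nm).

    Computed on leaflet-folded |z| profiles.  Positive values point toward
    the bilayer interior: depth = z_peak(glycerol) - z_peak(group) in folded
    coordinates.  The bootstrap resamples frames jointly for both peaks.
    """
    if group not in ("hydroxyl_oxygen", "terminal_methyl"):
        raise AnalysisError(f"unsupported group: {group}")
    gp = folded_profile(ens, {"species": species, "role": group}, bin_width)
    gly = folded_profile(ens, GLYCEROL_SEL, bin_width)
    half = float(gp.bin_edges[-1])

    def _depth(gdens, ydens):
        z_g = peak_z(_profile_like(gp, gdens), (0.0, half))
        z_y = peak_z(_profile_like(gly, ydens), (0.0, half))
        return z_y - z_g

    value = _depth(gp.density, gly.density)
    rng = _rng(seed, rng)
    nf = ens.n_frames
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        draws[b] = _depth(
            gp.per_frame_density[idx].mean(axis=0),
            gly.per_frame_density[idx].mean(axis=0),
        )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


# ---------------------------------------------------------------------------
# Desk-scale arithmetic on reported quantities
# ---------------------------------------------------------------------------


class SolventComposition(NamedTuple):
    n_alcohol: int
    n_water: int
    alcohol_per_lipid: float


def solvent_composition(
    conc_g_per_L: float,
    species: str,
    total_solvent: int = 5210,
    n_lipids: int = 128,
) -> SolventComposition:
    """Solvent molecule counts for a nominal aqueous alcohol concentration.

    The aqueous phase is built under the additive-volume convention: per
    litre of solution, ``conc`` grams of alcohol occupy conc/rho_alcohol mL
    and the remaining volume is water at its bulk density.  The alcohol mole
    fraction of that phase, applied to ``total_solvent`` molecules, gives the
    alcohol count; dividing by ``n_lipids`` gives the alcohol/lipid ratio.
    Above ~80 g/L the additive-volume and mass-per-litre conventions diverge
    noticeably, which is warned about but not an error.
    """
    if conc_g_per_L < 0:
        raise AnalysisError("concentration must be non-negative")
    if species not in ("ETHANOL", "BUTANOL"):
        raise AnalysisError(f"unsupported alcohol species: {species}")
    if conc_g_per_L >= 80:
        warnings.warn(
            "additive-volume and mass-per-litre solvent conventions diverge "
            f"at {conc_g_per_L} g/L",
            stacklevel=2,
        )
    v_alc_mL = conc_g_per_L / BULK_DENSITY_G_PER_ML[species]
    if v_alc_mL >= 1000.0:
        raise AnalysisError("concentration exceeds pure-alcohol density")
    m_water = (1000.0 - v_alc_mL) * BULK_DENSITY_G_PER_ML["WATER"]
    mol_alc = conc_g_per_L / MOLAR_MASS_G_PER_MOL[species]
    mol_water = m_water / MOLAR_MASS_G_PER_MOL["WATER"]
    x = mol_alc / (mol_alc + mol_water)
    n_alcohol = int(round(total_solvent * x))
    # the reported per-lipid ratio keeps the unrounded molecule count: the
    # printed two-decimal ratios follow the exact mole fraction, not the
    # integer count actually placed in a box
    return SolventComposition(
        n_alcohol=n_alcohol,
        n_water=total_solvent - n_alcohol,
        alcohol_per_lipid=total_solvent * x / float(n_lipids),
    )


def percent_change(control: float, treated: float, rounded: bool = True) -> float:
    """Percentage change of ``treated`` relative to ``control``.

    Reported to the nearest integer by default, matching how relative
    membrane-property changes are quoted.
    """
    if control == 0:
        raise AnalysisError("control value must be non-zero")
    value = 100.0 * (treated - control) / control
    return float(round(value)) if rounded else value


def aggregate_conditions(values) -> tuple[float, float]:
    """Mean and sample standard deviation over per-condition values.

    A single value yields an undefined (NaN) standard deviation.
    """
    x = np.asarray(list(values), dtype=float)
    if len(x) == 0:
        raise AnalysisError("no values to aggregate")
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
    return float(np.mean(x)), sd


def significant_difference(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """True iff two 95% intervals are disjoint (the significance call)."""
    return bool(a.upper < b.lower or b.upper < a.lower)


# ---------------------------------------------------------------------------
# Metric bundle
# ---------------------------------------------------------------------------


def compute_membrane_metrics(
    ens,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_boot: int = DEFAULT_N_BOOT,
    n_blocks: int = DEFAULT_N_BLOCKS,
    seed=None,
    lipids_per_leaflet: int | None = None,
) -> dict:
    """Compute every applicable membrane metric on one ensemble.

    Returns a report-ready mapping of metric name to IntervalEstimate (or an
    ``{"error": ...}`` entry when a metric's preconditions are not met, e.g.
    partitioning on an alcohol-free system).  One seeded random stream feeds
    all bootstraps, so the bundle is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    meta = ens.metadata
    if lipids_per_leaflet is None:
        lipids_per_leaflet = int(meta.get("n_lipids_per_leaflet", 64))
    results: dict = {}

    def _try(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:  # precondition failures become report entries
            results[name] = {"error": f"{type(exc).__name__}: {exc}"}

    _try("area_per_lipid_nm2", lambda: area_per_lipid(ens, lipids_per_leaflet, n_blocks))
    _try("thickness_nm", lambda: bilayer_thickness(ens, bin_width, n_blocks))

    def _scd():
        res = deuterium_order_parameters(ens, "IPC", 1, n_blocks)
        for ci, est in res.per_carbon.items():
            results[f"scd_carbon_{ci:02d}"] = est
        return res.chain_mean

    _try("scd_chain_mean", _scd)
    _try(
        "interior_water_count",
        lambda: interior_water_count(ens, bin_width, n_boot, rng=rng),
    )
    species_present = set(ens.table["species"].unique())
    n_lipids = int(meta.get("n_lipids_total", 2 * lipids_per_leaflet))
    for sp in ("ETHANOL", "BUTANOL"):
        if sp not in species_present:
            continue
        low = sp.lower()
        _try(
            f"partition_percent_{low}",
            lambda sp=sp: partition_fraction(ens, sp, bin_width, n_boot, rng=rng),
        )
        for group in ("hydroxyl_oxygen", "terminal_methyl"):
            _try(
                f"depth_{group}_{low}_nm",
                lambda sp=sp, g=group: insertion_depth(ens, sp, g, n_boot=n_boot, rng=rng),
            )
        n_alc = int(
            ens.table[
                (ens.table["species"] == sp)
                & (ens.table["role"] == "hydroxyl_oxygen")
                & (ens.table["frame"] == 0)
            ].shape[0]
        )
        results[f"alcohol_per_lipid_{low}"] = n_alc / float(n_lipids)
    return results
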