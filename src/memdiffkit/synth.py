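"""Synthetic-data generators with known ground truth.

Every analysis stage in this package can be exercised without any external
data: the generators below emit bilayer particle ensembles, radiotracer
uptake time courses and growth curves whose generating parameters are known
and recorded in a machine-readable truth record.  The ensembles are
*statistical mimics* — particles are drawn from the per-role distributions
that the estimators are defined on (Gaussian head-group layers, a uniform
acyl-tail slab, a bulk water phase with a ramp through the head groups,
alcohols split between a membrane layer and the bulk) with no bonded
dynamics or energetics.  That is deliberate: the artifact tests estimators,
not physics.

Default numeric scales follow the simulated reference system (128 lipids —
44 DOPC, 44 POPI, 20 IPC, 20 ergosterol — ~5200 solvent molecules,
phosphate peaks near +/-1.9 nm) so reports look dimensionally familiar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SpecError
from .particles import CONTROL_COMPOSITION, TABLE_COLUMNS, ParticleEnsemble
from .uptake import UptakeSample, undissociated_fraction

#: Carbon-1 to terminal-carbon lengths of the alcohols along their axis (nm).
ALCOHOL_LENGTH_NM = {"ETHANOL": 0.15, "BUTANOL": 0.37}

CH_BOND_NM = 0.109


@dataclass(frozen=True)
class AlcoholSpec:
    """Alcohol load and placement for the bilayer generator.

    ``membrane_fraction`` of the molecules sit in the head-group layer, with
    the hydroxyl oxygen ``hydroxyl_depth`` nm interior of the glycerol peak
    and the terminal methyl a further ``molecular_length`` nm interior on
    average; the rest are bulk.  ``molecular_length`` defaults to the
    species' carbon-backbone length (ethanol 0.15 nm, n-butanol 0.37 nm).
    """

    species: str
    n_molecules: int
    membrane_fraction: float
    hydroxyl_depth: float = 0.0
    hydroxyl_width: float = 0.15
    molecular_length: float | None = None
    orientation_noise: float = 0.05

    @property
    def length(self) -> float:
        if self.molecular_length is not None:
            return self.molecular_length
        return ALCOHOL_LENGTH_NM[self.species]


@dataclass
class BilayerSpec:
    """Generator parameters for a synthetic bilayer ensemble.

    Leaflet phosphate layers are Gaussians at +/-``phosphate_peak_z``; the
    POPI glycerol layer sits ``glycerol_offset`` nm inward.  IPC acyl chains
    span the tail slab (half-width ``tail_slab_halfwidth``), each carbon
    carrying two hydrogens whose tilt distribution is tuned so the expected
    deuterium order parameter of carbon i equals ``scd_target[i-1]``.  The
    interior water count per frame is Poisson(``interior_water_target``),
    drawn from the fixed pool of ``n_water`` waters; the remainder fill the
    bulk with a linear ramp through the head-group region (from
    ``ramp_start``, slightly outboard of the tail slab so ramp waters never
    blur the interior boundary, to ``water_ramp_end``), mimicking the water
    depletion profile of a real bilayer.
    """

    box_xy: float = 5.83
    box_xy_sd: float = 0.05
    box_z: float = 9.0
    n_frames: int = 100
    composition: dict[str, int] = field(
        default_factory=lambda: dict(CONTROL_COMPOSITION)
    )
    phosphate_peak_z: float = 1.9
    peak_width: float = 0.15
    phosphate_markers_per_lipid: int = 3
    glycerol_offset: float = 0.3
    tail_slab_halfwidth: float = 1.0
    n_tail_carbons: int = 16
    tail_chains: int = 2
    scd_target: tuple[float, ...] | None = None
    ch_jitter: float = 0.05
    n_water: int = 5000
    interior_water_target: int = 110
    water_ramp_start: float | None = None  # default: slab edge + 0.3 nm
    water_ramp_end: float = 2.6
    alcohol: AlcoholSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scd_target is None:
            n = self.n_tail_carbons
            # plateau order near the head group decaying toward the chain end
            self.scd_target = tuple(
                -(0.20 - 0.15 * i / max(n - 1, 1)) for i in range(n)
            )
        self.scd_target = tuple(float(s) for s in self.scd_target)

    @property
    def ramp_start(self) -> float:
        if self.water_ramp_start is not None:
            return self.water_ramp_start
        return self.tail_slab_halfwidth + 0.3

    def validate(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if min(self.composition.values(), default=0) < 0:
            raise SpecError("composition counts must be non-negative")
        if self.box_xy <= 0 or self.box_z <= 0 or self.box_xy_sd < 0:
            raise SpecError("box parameters must be positive")
        if self.peak_width <= 0:
            raise SpecError("peak widths must be positive")
        if not 0 < self.tail_slab_halfwidth < self.phosphate_peak_z:
            raise SpecError("tail slab must end inside the phosphate layer")
        if not self.phosphate_peak_z < self.water_ramp_end < self.box_z / 2:
            raise SpecError("water ramp must end between the peak and the box edge")
        if not self.tail_slab_halfwidth <= self.ramp_start < self.water_ramp_end:
            raise SpecError("water ramp must start between the slab edge and its end")
        if len(self.scd_target) != self.n_tail_carbons:
            raise SpecError("scd_target must list one value per tail carbon")
        if any(not -0.5 <= s <= 1.0 for s in self.scd_target):
            raise SpecError("scd_target values must lie in [-0.5, 1]")
        if self.interior_water_target > self.n_water:
            raise SpecError("interior_water_target exceeds n_water")
        if self.n_water < 0 or self.interior_water_target < 0:
            raise SpecError("water counts must be non-negative")
        a = self.alcohol
        if a is not None:
            if a.species not in ALCOHOL_LENGTH_NM:
                raise SpecError(f"unsupported alcohol species: {a.species}")
            if a.n_molecules < 0:
                raise SpecError("alcohol count must be non-negative")
            if not 0 <= a.membrane_fraction <= 1:
                raise SpecError("membrane_fraction must lie in [0, 1]")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "BilayerSpec":
        """A reduced ensemble for fast tests: fewer frames and waters."""
        base = cls(
            n_frames=25,
            n_water=1200,
            interior_water_target=40,
            seed=seed,
        )
        return replace(base, **overrides)


def draw_ch_cosines(s_target: float, n: int, rng, jitter: float = 0.05) -> np.ndarray:
    """Draw C-H bond cosines whose expected order parameter is ``s_target``.

    Single-parameter tilt family: |cos theta| = c + Normal(0, jitter) with a
    random sign, where c is chosen so that E[(3 cos^2 - 1)/2] = s_target
    (the jitter's second moment is absorbed into c).  This inversion is
    independent of the estimator, so direct averaging over the drawn bonds
    is a valid oracle for the S_CD estimator.
    """
    c2 = (2.0 * s_target + 1.0) / 3.0 - jitter**2
    c = math.sqrt(max(c2, 0.0))
    u = c + rng.normal(0.0, jitter, size=n)
    u *= rng.choice((-1.0, 1.0), size=n)
    return np.clip(u, -1.0, 1.0)


def _sample_bulk_water_abs_z(n, h, ramp_end, half_z, rng):
    """|z| for bulk waters: linear ramp on [h, ramp_end], flat beyond."""
    ramp_area = (ramp_end - h) / 2.0
    flat_area = half_z - ramp_end
    p_ramp = ramp_area / (ramp_area + flat_area)
    in_ramp = rng.random(n) < p_ramp
    out = np.empty(n)
    nr = int(in_ramp.sum())
    out[in_ramp] = h + (ramp_end - h) * np.sqrt(rng.random(nr))
    out[~in_ramp] = rng.uniform(ramp_end, half_z, size=n - nr)
    return out


def generate_bilayer_ensemble(spec: BilayerSpec) -> ParticleEnsemble:
    """Generate a labelled bilayer particle ensemble from a spec.

    Deterministic per ``spec.seed``.  The returned ensemble carries a
    ``metadata['truth']`` record of the generating parameters; estimators
    never read it.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition
    half_z = spec.box_z / 2.0
    gly_peak = spec.phosphate_peak_z - spec.glycerol_offset

    # ---- static identity layout (constant across frames) ----------------
    mol, species, role, chain, carbon, leaflet = [], [], [], [], [], []
    groups: dict[str, slice] = {}

    def _add(n, mol_ids, sp, rl, ch, ci, lf, tag=None):
        start = len(mol)
        mol.extend(mol_ids)
        species.extend([sp] * n)
        role.extend([rl] * n)
        chain.extend(ch if isinstance(ch, list) else [ch] * n)
        carbon.extend(ci if isinstance(ci, list) else [ci] * n)
        leaflet.extend(lf if isinstance(lf, list) else [lf] * n)
        if tag:
            groups[tag] = slice(start, len(mol))

    next_mol = 1
    lipid_ids: dict[str, list[int]] = {}
    for sp in ("DOPC", "POPI", "IPC", "ERG"):
        n = comp.get(sp, 0)
        lipid_ids[sp] = list(range(next_mol, next_mol + n))
        next_mol += n
    n_lipids = sum(comp.get(sp, 0) for sp in ("DOPC", "POPI", "IPC", "ERG"))

    def _leaflets(ids):
        # first half upper (+1), second half lower (-1)
        n = len(ids)
        return [1] * (n - n // 2) + [-1] * (n // 2)

    # phosphate markers on the phospholipids
    p_mols, p_leaf, p_species = [], [], []
    for sp in ("DOPC", "POPI", "IPC"):
        lf = _leaflets(lipid_ids[sp])
        for mid, s in zip(lipid_ids[sp], lf):
            for _ in range(spec.phosphate_markers_per_lipid):
                p_mols.append(mid)
                p_leaf.append(s)
                p_species.append(sp)
    start = len(mol)
    mol.extend(p_mols)
    species.extend(p_species)
    role.extend(["phosphate"] * len(p_mols))
    chain.extend([0] * len(p_mols))
    carbon.extend([0] * len(p_mols))
    leaflet.extend(p_leaf)
    groups["phosphate"] = slice(start, len(mol))

    # POPI glycerol backbone markers
    popi_leaf = _leaflets(lipid_ids["POPI"])
    _add(
        len(lipid_ids["POPI"]),
        lipid_ids["POPI"],
        "POPI",
        "glycerol_backbone",
        0,
        0,
        popi_leaf,
        tag="glycerol",
    )

    # ergosterol placeholder particles
    erg_leaf = _leaflets(lipid_ids["ERG"])
    _add(len(lipid_ids["ERG"]), lipid_ids["ERG"], "ERG", "other", 0, 0, erg_leaf, tag="erg")

    # IPC tail carbons and hydrogens
    ipc_leaf = _leaflets(lipid_ids["IPC"])
    c_mols, c_chain, c_idx, c_leaf, c_chain_seq = [], [], [], [], []
    chain_seq = 0
    for mid, s in zip(lipid_ids["IPC"], ipc_leaf):
        for ch_id in range(1, spec.tail_chains + 1):
            for ci in range(1, spec.n_tail_carbons + 1):
                c_mols.append(mid)
                c_chain.append(ch_id)
                c_idx.append(ci)
                c_leaf.append(s)
                c_chain_seq.append(chain_seq)
            chain_seq += 1
    n_chains = chain_seq
    c_chain_seq = np.asarray(c_chain_seq, dtype=int)
    start = len(mol)
    mol.extend(c_mols)
    species.extend(["IPC"] * len(c_mols))
    role.extend(["tail_carbon"] * len(c_mols))
    chain.extend(c_chain)
    carbon.extend(c_idx)
    leaflet.extend(c_leaf)
    groups["tail_carbon"] = slice(start, len(mol))
    # two hydrogens per carbon, referencing the carbon slots
    h_parent = np.repeat(np.arange(start, len(mol)), 2)
    start = len(mol)
    mol.extend(np.repeat(c_mols, 2).tolist())
    species.extend(["IPC"] * (2 * len(c_mols)))
    role.extend(["tail_hydrogen"] * (2 * len(c_mols)))
    chain.extend(np.repeat(c_chain, 2).tolist())
    carbon.extend(np.repeat(c_idx, 2).tolist())
    leaflet.extend(np.repeat(c_leaf, 2).tolist())
    groups["tail_hydrogen"] = slice(start, len(mol))

    # water
    water_ids = list(range(next_mol, next_mol + spec.n_water))
    next_mol += spec.n_water
    _add(spec.n_water, water_ids, "WATER", "water_oxygen", 0, 0, 0, tag="water")

    # alcohols: hydroxyl oxygen + terminal methyl per molecule
    alc = spec.alcohol
    n_alc = alc.n_molecules if alc else 0
    if n_alc:
        alc_ids = list(range(next_mol, next_mol + n_alc))
        next_mol += n_alc
        _add(n_alc, alc_ids, alc.species, "hydroxyl_oxygen", 0, 0, 0, tag="hydroxyl")
        _add(n_alc, alc_ids, alc.species, "terminal_methyl", 0, 0, 0, tag="methyl")

    P = len(mol)
    leaflet_arr = np.asarray(leaflet, dtype=float)
    carbon_arr = np.asarray(carbon, dtype=int)
    scd = np.asarray(spec.scd_target)

    # ---- per-frame coordinates ------------------------------------------
    boxes = np.empty((spec.n_frames, 3))
    xs = np.empty((spec.n_frames, P))
    ys = np.empty((spec.n_frames, P))
    zs = np.empty((spec.n_frames, P))
    for f in range(spec.n_frames):
        L = max(spec.box_xy + spec.box_xy_sd * rng.standard_normal(), 1.0)
        boxes[f] = (L, L, spec.box_z)
        x = rng.uniform(0.0, L, size=P)
        y = rng.uniform(0.0, L, size=P)
        z = np.zeros(P)

        g = groups["phosphate"]
        n = g.stop - g.start
        z[g] = leaflet_arr[g] * rng.normal(spec.phosphate_peak_z, spec.peak_width, n)

        g = groups["glycerol"]
        n = g.stop - g.start
        z[g] = leaflet_arr[g] * rng.normal(gly_peak, spec.peak_width, n)

        g = groups["erg"]
        n = g.stop - g.start
        z[g] = leaflet_arr[g] * rng.uniform(0.5, spec.phosphate_peak_z, n)

        g = groups["tail_carbon"]
        n = g.stop - g.start
        frac = (carbon_arr[g] - 0.5) / spec.n_tail_carbons
        z[g] = leaflet_arr[g] * (
            spec.tail_slab_halfwidth * (1.0 - frac) + rng.normal(0.0, 0.03, n)
        )
        # carbons of one chain share a lateral anchor so the chain axis is
        # geometrically coherent (needed by the hydrogen-free S_CD fallback)
        chain_x0 = rng.uniform(0.0, L, n_chains)
        chain_y0 = rng.uniform(0.0, L, n_chains)
        x[g] = chain_x0[c_chain_seq] + rng.normal(0.0, 0.05, n)
        y[g] = chain_y0[c_chain_seq] + rng.normal(0.0, 0.05, n)

        g = groups["tail_hydrogen"]
        n = g.stop - g.start
        cos = np.empty(n)
        for ci in range(1, spec.n_tail_carbons + 1):
            m = carbon_arr[g] == ci
            cos[m] = draw_ch_cosines(scd[ci - 1], int(m.sum()), rng, spec.ch_jitter)
        sin = np.sqrt(np.clip(1.0 - cos**2, 0.0, 1.0))
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        x[g] = x[h_parent] + CH_BOND_NM * sin * np.cos(phi)
        y[g] = y[h_parent] + CH_BOND_NM * sin * np.sin(phi)
        z[g] = z[h_parent] + CH_BOND_NM * cos

        g = groups["water"]
        n = g.stop - g.start
        n_int = min(int(rng.poisson(spec.interior_water_target)), n)
        zw = np.empty(n)
        zw[:n_int] = rng.uniform(-spec.tail_slab_halfwidth, spec.tail_slab_halfwidth, n_int)
        bulk_abs = _sample_bulk_water_abs_z(
            n - n_int, spec.ramp_start, spec.water_ramp_end, half_z - 0.05, rng
        )
        zw[n_int:] = bulk_abs * rng.choice((-1.0, 1.0), size=n - n_int)
        z[g] = zw

        if n_alc:
            gh = groups["hydroxyl"]
            gm = groups["methyl"]
            in_mem = rng.random(n_alc) < alc.membrane_fraction
            sign = rng.choice((-1.0, 1.0), size=n_alc)
            zh = np.empty(n_alc)
            zm = np.empty(n_alc)
            nm = int(in_mem.sum())
            zh[in_mem] = rng.normal(
                gly_peak - alc.hydroxyl_depth, alc.hydroxyl_width, nm
            )
            zm[in_mem] = zh[in_mem] - alc.length + rng.normal(
                0.0, alc.orientation_noise, nm
            )
            nb = n_alc - nm
            zh[~in_mem] = rng.uniform(spec.water_ramp_end + 0.2, half_z - 0.1, nb)
            zm[~in_mem] = zh[~in_mem] + rng.uniform(-alc.length, alc.length, nb)
            z[gh] = sign * zh
            z[gm] = sign * zm
            x[gm] = x[gh] + rng.normal(0.0, 0.05, n_alc)
            y[gm] = y[gh] + rng.normal(0.0, 0.05, n_alc)

        # emit exactly recentered frames: phosphate COM at z = 0
        gp = groups["phosphate"]
        z -= z[gp].mean()
        xs[f] = x % L
        ys[f] = y % L
        zs[f] = z
    # ---- assemble the table ---------------------------------------------
    table = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(spec.n_frames), P),
            "mol_id": np.tile(np.asarray(mol, dtype=int), spec.n_frames),
            "species": np.tile(np.asarray(species, dtype=object), spec.n_frames),
            "role": np.tile(np.asarray(role, dtype=object), spec.n_frames),
            "chain_id": np.tile(np.asarray(chain, dtype=int), spec.n_frames),
            "carbon_index": np.tile(carbon_arr, spec.n_frames),
            "x": xs.ravel(),
            "y": ys.ravel(),
            "z": zs.ravel(),
        }
    )[list(TABLE_COLUMNS)]
    truth = {
        "area_per_lipid_nm2": spec.box_xy**2 / max(n_lipids // 2, 1),
        "thickness_nm": 2.0 * spec.phosphate_peak_z,
        "glycerol_peak_nm": gly_peak,
        "scd_target": list(spec.scd_target),
        "scd_chain_mean": float(np.mean(np.abs(scd[1:-1]))),
        "interior_water_count": float(spec.interior_water_target),
    }
    if alc:
        truth.update(
            {
                "alcohol_species": alc.species,
                "partition_percent": 100.0 * alc.membrane_fraction,
                "depth_hydroxyl_oxygen_nm": alc.hydroxyl_depth,
                "depth_terminal_methyl_nm": alc.hydroxyl_depth + alc.length,
            }
        )
    metadata = {
        "n_lipids_total": n_lipids,
        "n_lipids_per_leaflet": n_lipids // 2,
        "composition": dict(comp),
        "generator_seed": spec.seed,
        "truth": truth,
    }
    if alc:
        metadata["alcohol_species"] = alc.species
        metadata["n_alcohol"] = n_alc
    ens = ParticleEnsemble(table, boxes, metadata)
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# Uptake time courses
# ---------------------------------------------------------------------------


@dataclass
class UptakeSpec:
    """First-order equilibration uptake time course with counting noise.

    The intracellular total acid follows C_in(t) = A_target * c_out *
    (1 - exp(-k t)); an aliquot's expected counts are the calibration slope
    times the nmol retained plus the condition blank and the natural
    background, with Poisson counting noise when ``poisson_noise`` is set.
    """

    condition_id: str = "control"
    c_out_mM: float = 2.0
    A_target: float = 9.0
    k_per_s: float = 0.01
    timepoints_s: tuple[float, ...] = (15.0, 40.0, 70.0, 300.0, 600.0)
    cal_slope_cpm_per_nmol: float = 200.0
    background_cpm: float = 30.0
    blank_cpm: float = 50.0
    aliquot_dry_weight_mg: float = 0.5
    cell_volume_uL_per_mg: float = 2.0
    replicates: int = 3
    n_standards: int = 6
    poisson_noise: bool = True
    ph_out: float = 5.0
    pka: float = 4.8
    seed: int = 0

    def validate(self) -> None:
        positive = (
            self.c_out_mM,
            self.A_target,
            self.k_per_s,
            self.cal_slope_cpm_per_nmol,
            self.aliquot_dry_weight_mg,
            self.cell_volume_uL_per_mg,
        )
        if any(v <= 0 for v in positive):
            raise SpecError("uptake spec scales must be positive")
        if self.background_cpm < 0 or self.blank_cpm < 0:
            raise SpecError("counting offsets must be non-negative")
        if self.replicates < 1 or self.n_standards < 2:
            raise SpecError("need >= 1 replicate and >= 2 standards")
        if not self.timepoints_s or min(self.timepoints_s) <= 0:
            raise SpecError("timepoints must be positive")
        f_out = undissociated_fraction(self.ph_out, self.pka)
        if self.A_target <= f_out:
            raise SpecError(
                f"A_target must exceed the equilibrium floor {f_out:.3f}"
            )


def generate_uptake_timecourse(spec: UptakeSpec):
    """Generate (samples, standards, truth) for one uptake condition.

    ``standards`` are (nmol, cpm) pairs spanning the signal range, carrying
    the same counting noise model as the samples.  Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def _count(expected: float) -> float:
        if spec.poisson_noise:
            return float(rng.poisson(expected))
        return float(expected)

    plateau_mM = spec.A_target * spec.c_out_mM
    samples = []
    for rep in range(spec.replicates):
        for t in spec.timepoints_s:
            conc = plateau_mM * (1.0 - math.exp(-spec.k_per_s * t))
            nmol = (
                conc * spec.cell_volume_uL_per_mg * spec.aliquot_dry_weight_mg
            )  # mM * uL = nmol
            expected = (
                spec.cal_slope_cpm_per_nmol * nmol
                + spec.blank_cpm
                + spec.background_cpm
            )
            samples.append(
                UptakeSample(
                    condition_id=spec.condition_id,
                    time_s=float(t),
                    cpm=_count(expected),
                    cell_dry_weight_mg=spec.aliquot_dry_weight_mg,
                    extracellular_mM=spec.c_out_mM,
                    replicate=rep,
                )
            )
    nmol_max = plateau_mM * spec.cell_volume_uL_per_mg * spec.aliquot_dry_weight_mg
    standards = []
    for nmol in np.linspace(nmol_max / spec.n_standards, 1.2 * nmol_max, spec.n_standards):
        expected = spec.cal_slope_cpm_per_nmol * nmol + spec.background_cpm
        standards.append((float(nmol), _count(expected)))
    truth = {
        "condition_id": spec.condition_id,
        "A_target": spec.A_target,
        "k_per_s": spec.k_per_s,
        "c_out_mM": spec.c_out_mM,
        "plateau_mM": plateau_mM,
        "cal_slope_cpm_per_nmol": spec.cal_slope_cpm_per_nmol,
        "blank_cpm": spec.blank_cpm,
        "background_cpm": spec.background_cpm,
    }
    return samples, standards, truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass
class GrowthSpec:
    """Batch growth with an exponential phase and a programmed diauxic dip.

    The instantaneous growth rate runs at ``mu`` during the glucose phase,
    dips smoothly to ``r_min`` exactly at ``t_dip`` (Gaussian dip of width
    ``dip_width_h``) and recovers to the slower respiratory rate ``mu2``.
    OD noise is multiplicative log-normal with sd ``noise_sd``.
    """

    od0: float = 0.2
    mu: float = 0.35
    mu2: float = 0.12
    r_min: float = 0.02
    t_dip: float = 7.7
    dip_width_h: float = 0.5
    sampling_interval_h: float = 0.25
    noise_sd: float = 0.01
    duration_h: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        if self.od0 <= 0:
            raise SpecError("od0 must be positive")
        if self.mu < 0 or self.mu2 < 0 or self.noise_sd < 0:
            raise SpecError("rates and noise must be non-negative")
        if self.sampling_interval_h <= 0 or self.duration_h <= 0:
            raise SpecError("sampling interval and duration must be positive")
        if self.mu > 0 and self.duration_h <= self.t_dip:
            raise SpecError("duration must exceed t_dip for growth cases")


def generate_growth_curve(spec: GrowthSpec):
    """Generate (times_h, od, truth) for one growth condition."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_h + 1e-9, spec.sampling_interval_h)
    if spec.mu <= 0:
        od = spec.od0 * np.exp(rng.normal(0.0, spec.noise_sd, len(t)))
        return t, od, {"mu": 0.0, "t_dip": None}
    dip = np.exp(-((t - spec.t_dip) ** 2) / (2.0 * spec.dip_width_h**2))
    base = np.where(t <= spec.t_dip, spec.mu, spec.mu2)
    rate = base - (base - spec.r_min) * dip
    ln_od = np.log(spec.od0) + np.concatenate(
        ([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t)))
    )
    od = np.exp(ln_od + rng.normal(0.0, spec.noise_sd, len(t)))
    return t, od, {"mu": spec.mu, "t_dip": spec.t_dip}
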