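"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from memdiffkit.particles import TABLE_COLUMNS, ParticleEnsemble
from memdiffkit.synth import AlcoholSpec, BilayerSpec, generate_bilayer_ensemble


def make_ensemble(z_per_frame, box=(5.0, 5.0, 10.0), species="WATER", role="water_oxygen"):
    """Build a minimal ensemble with given per-frame z coordinates.

    ``z_per_frame`` is a list of 1-D arrays (one per frame); x, y are spread
    deterministically inside the box.
    """
    rows = []
    for fi, zf in enumerate(z_per_frame):
        zf = np.asarray(zf, dtype=float)
        for pi, z in enumerate(zf):
            rows.append(
                (
                    fi,
                    pi + 1,
                    species,
                    role,
                    0,
                    0,
                    (0.1 + 0.37 * pi) % box[0],
                    (0.2 + 0.53 * pi) % box[1],
                    z,
                )
            )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    boxes = np.tile(np.asarray(box, dtype=float), (len(z_per_frame), 1))
    return ParticleEnsemble(table, boxes)


def add_particles(ens, species, role, z_values, mol_start=900000):
    """Return a copy of ``ens`` with extra particles at fixed z in every frame."""
    rows = []
    for fi in range(ens.n_frames):
        for pi, z in enumerate(np.asarray(z_values, dtype=float)):
            rows.append(
                (
                    fi,
                    mol_start + pi,
                    species,
                    role,
                    0,
                    0,
                    (0.3 + 0.41 * pi) % ens.boxes[fi][0],
                    (0.1 + 0.29 * pi) % ens.boxes[fi][1],
                    z,
                )
            )
    extra = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    table = (
        pd.concat([ens.table, extra], ignore_index=True)
        .sort_values("frame", kind="stable")
        .reset_index(drop=True)
    )
    return ParticleEnsemble(table, ens.boxes.copy(), dict(ens.metadata))


@pytest.fixture(scope="session")
def butanol_ensemble():
    """One small alcohol-loaded bilayer ensemble shared across tests."""
    spec = BilayerSpec.small(
        seed=7,
        n_frames=40,
        alcohol=AlcoholSpec("BUTANOL", 160, 0.9, hydroxyl_depth=0.03),
    )
    return generate_bilayer_ensemble(spec)


@pytest.fixture(scope="session")
def plain_ensemble():
    """A small alcohol-free bilayer ensemble."""
    return generate_bilayer_ensemble(BilayerSpec.small(seed=11, n_frames=30))
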