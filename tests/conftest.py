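"""Shared fixtures: planted proteomes, reference panels, toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from lipmine import (
    PlantedCandidate,
    ProteomeSpec,
    ProteinRecord,
    ToyStructureSpec,
    TunnelParams,
    generate_proteome,
    generate_structure,
)

# Tunnel parameters suited to CA-only toys (smaller united-atom radius and
# probe than the full-atom defaults).
TOY_TUNNEL_PARAMS = TunnelParams(grid_step=0.6, probe_radius=0.8, atom_radius=1.0)


def make_plants(n: int, signal_len: int = 15) -> list[PlantedCandidate]:
    return [
        PlantedCandidate(
            oxyanion_pos=40 + 3 * i,
            shoulder_pos=130 + 5 * i,
            cys_positions=(62 + i, 99 + i),
            lid_hydrophobic_count=6 + i,
            triad_glu_pos=160 + 3 * i,
            triad_his_pos=190 + 3 * i,
            sequon_count=1 + i % 3,
            signal_len=signal_len,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_proteome():
    spec = ProteomeSpec(n_background=60, n_planted=3, seed=11, length_range=(120, 260))
    plants = make_plants(3)
    records, truth = generate_proteome(spec, plants)
    return spec, plants, records, truth


@pytest.fixture(scope="session")
def straight_toy():
    toy = generate_structure(ToyStructureSpec(seed=5))
    return toy


@pytest.fixture(scope="session")
def bent_toy():
    return generate_structure(
        ToyStructureSpec(seed=5, bend_angle=90.0, tunnel_length=40.0,
                         lattice_jitter=0.1, n_shell_residues=3000)
    )


def mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Point-mutate a fraction of positions (used by phylo placement tests)."""
    from lipmine.records import STANDARD_AA

    letters = list(seq)
    n_mut = int(round(fraction * len(letters)))
    sites = rng.choice(len(letters), size=n_mut, replace=False)
    for s in sites:
        choices = [c for c in STANDARD_AA if c != letters[s]]
        letters[s] = choices[rng.integers(len(choices))]
    return "".join(letters)


def family_panel(rng: np.random.Generator, versatile_count: int = 2):
    """Synthetic reference panel: 4 families of related sequences."""
    from lipmine.phylo import ReferencePanel

    base_len = 180
    founders = {
        "crugosa_like": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), base_len)),
        "yarrowia": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), base_len)),
        "brefeldin": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), base_len)),
        "pancreatic": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), base_len)),
    }
    records, families, versatile = [], {}, set()
    for fam, founder in founders.items():
        for j in range(3):
            rid = f"{fam}_{j}"
            seq = mutate(founder, 0.05 * j, rng)
            records.append(ProteinRecord(id=rid, seq=seq,
                                         description=f"family={fam}"))
            families[rid] = fam
            if fam == "crugosa_like" and j < versatile_count:
                versatile.add(rid)
    return ReferencePanel(records=tuple(records), families=families,
                          versatile=frozenset(versatile))
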