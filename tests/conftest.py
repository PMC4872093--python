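import numpy as np
import pytest
from hypothesis import settings

from ispkit import struct_io as sio
from ispkit import synthetic as syn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def frame_over(model, n, anchor_index):
    """Target frame covering all n base pairs, +1 at `anchor_index`."""
    start = 1 if anchor_index == 0 else -anchor_index
    return sio.assign_target_frame(model, "N" * n, ("D", anchor_index + 1, ""),
                                   target_start=start)


def positions_for(n, anchor_index):
    start = 1 if anchor_index == 0 else -anchor_index
    return sio.position_run(start, n)


@pytest.fixture(scope="session")
def straight_duplex():
    seq = "GCTAGCTAGCATCGATCGATCGAT"
    model, truth = syn.make_duplex(syn.DuplexSpec(sequence=seq))
    frame = frame_over(model, len(seq), 11)
    return model, frame, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_complex(seed, n_plants=4, seq="GCTAGCTAGCATCGATCGATCGAT"):
    """Duplex plus pseudo protein residues planted at random distances.

    Returns (model, frame, planted ground truth).  Distances straddle the
    3.5 Å hydrogen-bond cutoff so detector tests see both sides.
    """
    rng = np.random.default_rng(seed)
    model, _ = syn.make_duplex(syn.DuplexSpec(sequence=seq))
    frame = frame_over(model, len(seq), 11)
    donor_atoms = {"LYS": "NZ", "ARG": "NH1", "ASN": "ND2", "SER": "OG"}
    base_atoms = {"A": ["N7", "N6", "N3"], "G": ["N7", "O6", "N3"],
                  "T": ["O4", "O2"], "C": ["N4", "O2"]}
    plants = []
    used = set()
    k = 0
    while len(plants) < n_plants:
        i = int(rng.integers(2, len(seq) - 2))
        strand = "top" if rng.random() < 0.5 else "bottom"
        if (i, strand) in used:
            continue
        base = seq[i] if strand == "top" else \
            {"A": "T", "T": "A", "G": "C", "C": "G"}[seq[i]]
        atom = base_atoms[base][int(rng.integers(len(base_atoms[base])))]
        resname = list(donor_atoms)[int(rng.integers(len(donor_atoms)))]
        dist = float(rng.uniform(2.7, 4.3))
        plant = syn.ContactPlant(resname, 100 + k, donor_atoms[resname],
                                 i, strand, atom, round(dist, 3))
        try:  # buried atoms may admit no clash-free placement; redraw
            syn.plant_contacts(model, plants + [plant])
        except syn.SpecError:
            continue
        used.add((i, strand))
        plants.append(plant)
        k += 1
    planted_model, truth = syn.plant_contacts(model, plants)
    return planted_model, frame, truth
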