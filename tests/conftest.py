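"""Shared fixtures: bundled references and small simulated plates.

Everything is generated in memory at session scope; no data files.
"""

import numpy as np
import pytest

import plate5p as p
from plate5p.simulate import SimulationConfig, simulate_plate

#: dilution factor putting bundled spike-ins at ~100 molecules/well, i.e.
#: roughly 5% of a 2,000-molecule cell — the design target for spike content
DESK_DILUTION = 2e6 * 430


@pytest.fixture(scope="session")
def germline():
    return p.bundled_germline()


@pytest.fixture(scope="session")
def transcriptome():
    return p.bundled_transcriptome()


@pytest.fixture(scope="session")
def spikeins():
    return p.bundled_spikeins()


@pytest.fixture(scope="session")
def whitelist():
    return p.bundled_whitelist()


@pytest.fixture(scope="session")
def layout(whitelist):
    return p.PlateLayout("P1", whitelist)


@pytest.fixture(scope="session")
def clean_plate(transcriptome, spikeins, layout, germline):
    """Error-free, duplication-free plate: the conservation oracle setting."""
    cfg = SimulationConfig(
        seed=11,
        cells_per_plate=8,
        mean_molecules_per_cell=800,
        spikein_dilution_factor=DESK_DILUTION,
        pcr_duplication_mean=1.0,
        seq_error_rate=0.0,
        receptor_mode="none",
    )
    return cfg, simulate_plate(cfg, transcriptome, spikeins, layout, germline)


@pytest.fixture(scope="session")
def noisy_plate(transcriptome, spikeins, layout, germline):
    """Plate with PCR duplication and sequencing error."""
    cfg = SimulationConfig(
        seed=13,
        cells_per_plate=6,
        mean_molecules_per_cell=500,
        spikein_dilution_factor=DESK_DILUTION,
        pcr_duplication_mean=4.0,
        seq_error_rate=1e-3,
        receptor_mode="none",
    )
    return cfg, simulate_plate(cfg, transcriptome, spikeins, layout, germline)


@pytest.fixture(scope="session")
def bcr_plate(transcriptome, spikeins, layout, germline):
    """Small B-cell plate with receptors, SHM 1%, sequencing error 1e-3."""
    cfg = SimulationConfig(
        seed=17,
        cells_per_plate=6,
        mean_molecules_per_cell=200,
        genes=20,
        spikein_dilution_factor=DESK_DILUTION * 10,
        pcr_duplication_mean=4.0,
        seq_error_rate=1e-3,
        receptor_mode="BCR",
        shm_rate=0.01,
        receptor_molecules_heavy=50,
        receptor_molecules_light=100,
    )
    return cfg, simulate_plate(cfg, transcriptome, spikeins, layout, germline)


@pytest.fixture(scope="session")
def demuxed_clean(clean_plate, layout):
    cfg, plate = clean_plate
    cells, report = p.demultiplex(plate.read1, plate.read2, layout)
    return cells, report
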