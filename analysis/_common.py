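"""Shared locations and lazy data generation for the numbered analysis drivers."""

from pathlib import Path

from endoshrink.synthetic import SimConfig, simulate_dataset

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "scratch" / "simdata"
RESULTS_DIR = ROOT / "results"

#: study conditions of the whole analysis: 50 ortholog sets over 6 OIE + 6
#: nonOIE species, OIE length-jitter SD 10 aa vs nonOIE 2 aa, 80% of indels
#: in the terminal 10% of the sequence, large accessories only in nonOIE.
CONFIG = SimConfig(seed=7)


def ensure_data() -> Path:
    if not (DATA_DIR / "groups.txt").exists():
        simulate_dataset(CONFIG, DATA_DIR)
    return DATA_DIR
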