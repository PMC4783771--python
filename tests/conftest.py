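import numpy as np
import pytest
import yaml

from cellkin import GrowthCurve, IndexMeasurement, KineticConstants


@pytest.fixture
def exact_curve():
    """Noiseless exponential curve: N(t) = 150000 * exp(0.03 t), 3 replicates."""
    t = np.arange(0.0, 145.0, 24.0)
    counts = {f"r{i}": 150000.0 * np.exp(0.03 * t) for i in (1, 2, 3)}
    return GrowthCurve("LINE_A", "standard", t, counts)


@pytest.fixture
def paired_indices():
    mi = IndexMeasurement("mitotic", 30, 1000, "LINE_A", "standard")
    ai = IndexMeasurement("apoptotic", 0, 1000, "LINE_A", "standard")
    return mi, ai


@pytest.fixture
def constants():
    return KineticConstants(T_M_h=1.0, T_A_h=3.0)


@pytest.fixture
def demo_config(tmp_path):
    """A small two-group scenario config file (YAML)."""
    cfg = {
        "seed": 7,
        "sampling": {
            "n_scored": 1000,
            "n_chambers": 4,
            "chamber_fraction": 1.0e-4,
            "days": [0, 1, 2, 3, 4, 5, 6],
            "replicates": 3,
        },
        "groups": [
            {"cell_line": "LINE_A", "condition": "standard", "b": 0.04,
             "d_detected": 0.005, "d_hidden": 0.010, "N0": 150000.0},
            {"cell_line": "LINE_B", "condition": "standard", "b": 0.035,
             "d_detected": 0.005, "d_hidden": 0.0, "N0": 150000.0},
        ],
        "globals": {"mi_convention": "flux", "bootstrap_B": 300,
                    "reference_line": "LINE_B"},
    }
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


@pytest.fixture
def growth_csv(tmp_path):
    path = tmp_path / "growth.csv"
    path.write_text(
        "cell_line,condition,replicate,time_h,count\n"
        "LINE_A,standard,r1,0,100\n"
        "LINE_A,standard,r1,24,200\n"
        "LINE_A,standard,r1,48,400\n"
    )
    return path


@pytest.fixture
def index_csv(tmp_path):
    path = tmp_path / "index.csv"
    path.write_text(
        "cell_line,condition,replicate,kind,positives,total\n"
        "LINE_A,standard,r1,mitotic,41,1000\n"
        "LINE_A,standard,r1,apoptotic,10,1000\n"
    )
    return path
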