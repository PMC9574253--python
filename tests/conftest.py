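import numpy as np
import pandas as pd
import pytest

from ovitherm.io import MISSING, GenotypeMatrix


def make_geno(calls, chrom=None, pos=None, ref=None, alt=None,
              breed=None, location=None):
    """GenotypeMatrix from a plain list of lists of dosages."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        calls=calls,
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 1000,
                     dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * m, dtype=object),
        breed=breed, location=location,
    )


@pytest.fixture
def toy_geno():
    """3 samples x 3 markers with one missing call."""
    return make_geno([[0, 1, 2], [1, 1, MISSING], [2, 1, 0]])


@pytest.fixture
def physio_panel():
    """4 animals, paired rest/stress rows, stress elevated for animal a0 only."""
    rows = []
    rng = np.random.default_rng(42)
    rest = {
        "RT": [38.5, 38.7, 38.9, 38.6], "ET": [35.0, 35.4, 35.8, 35.2],
        "RR": [30.0, 34.0, 38.0, 32.0], "GV": [6.0, 7.0, 8.0, 6.5],
        "VO2": [0.05, 0.055, 0.06, 0.052], "VCO2": [0.04, 0.045, 0.05, 0.042],
        "BW": [40.0, 45.0, 50.0, 42.0],
    }
    for i in range(4):
        base = {k: rest[k][i] for k in rest}
        rows.append({"animal_id": f"a{i}", "timepoint": "rest", **base})
        stress = dict(base)
        if i == 0:
            stress = {"RT": base["RT"] + 2.0, "ET": base["ET"] + 3.0,
                      "RR": base["RR"] + 60.0, "GV": base["GV"] + 2.0,
                      "VO2": base["VO2"] + 0.04, "VCO2": base["VCO2"] + 0.03,
                      "BW": base["BW"]}
        rows.append({"animal_id": f"a{i}", "timepoint": "stress", **stress})
    return pd.DataFrame(rows)
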