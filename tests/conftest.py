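import numpy as np
import pandas as pd
import pytest

from rbpscreen.io import ArrayScan, SpotRecord


@pytest.fixture
def tiny_scan() -> ArrayScan:
    """Three proteins x two duplicate spots, two channels."""
    records = []
    signals = {"P1": (100.0, 120.0), "P2": (50.0, 70.0), "P3": (80.0, 80.0)}
    for fid, (a, b) in signals.items():
        records.append(SpotRecord(fid, 1, {"Cy3": a, "Cy5": a + 1}))
        records.append(SpotRecord(fid, 2, {"Cy3": b, "Cy5": b + 1}))
    return ArrayScan("arr1", records, ["Cy3", "Cy5"])


@pytest.fixture
def plain_tsv(tmp_path):
    """Writer for small plain-TSV array tables."""
    def _write(rows, header, name="scan.tsv"):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_feature_table(rng, n_features=200, n_arrays=5, seed=None) -> pd.DataFrame:
    """Log-normal feature x array table with no structure."""
    g = np.random.default_rng(seed) if seed is not None else rng
    data = np.exp(g.normal(6.0, 1.0, size=(n_features, n_arrays)))
    return pd.DataFrame(data,
                        index=[f"F{i:04d}" for i in range(n_features)],
                        columns=[f"rep{j+1}" for j in range(n_arrays)])
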