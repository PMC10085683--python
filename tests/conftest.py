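import numpy as np
import pandas as pd
import pytest

from chromonema import ContactPairs


@pytest.fixture
def toy_pairs_factory():
    """Build a ContactPairs object from (chrom1, pos1, chrom2, pos2) tuples."""

    def make(records, chrom_sizes):
        if records:
            c1, p1, c2, p2 = zip(*records)
        else:
            c1, p1, c2, p2 = (), (), (), ()
        df = pd.DataFrame({
            "chrom1": list(c1), "pos1": np.asarray(p1, np.int64),
            "chrom2": list(c2), "pos2": np.asarray(p2, np.int64),
        })
        return ContactPairs(df=df, chrom_sizes=dict(chrom_sizes))

    return make


@pytest.fixture
def pairs_file_factory(tmp_path):
    """Write a .pairs text file and return its path."""

    def make(lines, name="toy.pairs"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return make
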