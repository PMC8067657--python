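import numpy as np
import pandas as pd
import pytest

from phycobycatch import (
    CountTable,
    PlateLayout,
    Well,
    io_formats,
    read_tree,
)


@pytest.fixture
def four_tip_tree(tmp_path):
    """Two cherries with unit branches: ((A:1,B:1):1,(C:1,D:1):1);"""
    path = tmp_path / "tree.nwk"
    path.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
    return read_tree(path)


@pytest.fixture
def small_counts():
    return CountTable(pd.DataFrame(
        [[50, 30, 20, 0], [0, 10, 60, 30], [25, 25, 25, 25]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3", "f4"],
    ))


@pytest.fixture
def corner_layout():
    return PlateLayout({"s1": Well("A", 1), "s2": Well("A", 2), "s3": Well("B", 1)})


def random_plate(rng, n_samples=96, n_features=50):
    """A full random plate: relative-abundance table plus its layout."""
    from phycobycatch.decontam import to_relative_abundance

    wells = [Well(r, c) for r in io_formats.PLATE_ROWS for c in range(1, 13)]
    wells = wells[:n_samples]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    layout = PlateLayout(dict(zip(samples, wells)))
    counts = rng.integers(0, 500, size=(n_samples, n_features))
    counts[rng.random(counts.shape) < 0.5] = 0
    table = CountTable(pd.DataFrame(
        counts, index=samples, columns=[f"f{j}" for j in range(n_features)]))
    return to_relative_abundance(table), layout
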