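import numpy as np
import pytest

from sortscreen.screen_io import BinCountTable, GuideLibrary


@pytest.fixture
def small_library() -> GuideLibrary:
    """3 genes x 2 guides + 2 controls."""
    ids = [f"g{i}_{j}" for i in range(3) for j in (1, 2)] + ["ctrl_1", "ctrl_2"]
    genes = [f"gene{i}" for i in range(3) for _ in (1, 2)] + ["", ""]
    ctrl = [False] * 6 + [True] * 2
    return GuideLibrary(np.array(ids, object), np.array(genes, object), np.array(ctrl))


@pytest.fixture
def small_table(small_library) -> BinCountTable:
    rng = np.random.default_rng(123)
    counts = rng.multinomial(200, [0.25] * 4, size=(2, small_library.n_guides))
    return BinCountTable(counts, small_library.guide_id, ["rep1", "rep2"],
                         ["bin1", "bin2", "bin3", "bin4"])
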