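import numpy as np
import pandas as pd
import pytest

from methdyn import (
    MethylationTimeCourse,
    SimulationConfig,
    SyntheticStudy,
    TimeCourseDesign,
    build_timecourse,
)


def make_timecourse(meth, total, labels=("0h", "1h", "24h", "96h"), chrom="chr1"):
    """Build a MethylationTimeCourse directly from count matrices."""
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n = meth.shape[0]
    sites = pd.DataFrame({"chrom": chrom, "pos": np.arange(n, dtype=np.int64) * 10})
    for j, l in enumerate(labels):
        sites[f"meth_{l}"] = meth[:, j]
        sites[f"total_{l}"] = total[:, j]
        sites[f"frac_{l}"] = meth[:, j] / total[:, j]
    design = TimeCourseDesign(labels=tuple(labels), min_coverage=1)
    return MethylationTimeCourse(design=design, sites=sites)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across read-only tests."""
    return SyntheticStudy(SimulationConfig(seed=11, n_cpgs=8000, n_genes=120, island_count=80))


@pytest.fixture(scope="session")
def small_timecourse(small_study):
    tables, _ = small_study.wgbs()
    return build_timecourse(tables, TimeCourseDesign())
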