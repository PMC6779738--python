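import shutil
from importlib.resources import files
from pathlib import Path

import numpy as np
import pytest

from stockshift import HaplotypeCounts, generate_panel, pairwise_differences


@pytest.fixture(scope="session")
def small_panel():
    """Six synthetic 474-bp haplotypes with all pairwise distances positive."""
    return generate_panel(6, seed=11)


@pytest.fixture(scope="session")
def distances6(small_panel):
    return pairwise_differences(small_panel)


@pytest.fixture()
def scenario_dir(tmp_path: Path) -> Path:
    """Writable copy of the packaged frozen synthetic scenario."""
    src = Path(str(files("stockshift.data") / "synthetic_scenario"))
    dst = tmp_path / "scenario"
    shutil.copytree(src, dst)
    return dst


def amova_phi_oracle(group_counts: list[dict], distances) -> float:
    """Individual-level two-group AMOVA phi-ST by explicit double loops.

    Independent of the package's quadratic-form implementation: expands
    counts to individuals and accumulates sums of squared distances pairwise.
    """
    idx = {h: i for i, h in enumerate(distances.labels)}
    groups = [
        [idx[h] for h, c in counts.items() for _ in range(c)] for counts in group_counts
    ]
    individuals = [i for g in groups for i in g]
    N = len(individuals)
    G = len(groups)
    d2 = distances.values

    def ssd(members):
        total = 0.0
        for a in members:
            for b in members:
                total += d2[a, b]
        return total / (2 * len(members))

    ssd_total = ssd(individuals)
    ssd_within = sum(ssd(g) for g in groups)
    sigma_w = ssd_within / (N - G)
    ms_among = (ssd_total - ssd_within) / (G - 1)
    sizes = np.array([len(g) for g in groups])
    n_prime = (N - (sizes**2).sum() / N) / (G - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    return sigma_a / (sigma_a + sigma_w)


@pytest.fixture(scope="session")
def phi_oracle():
    return amova_phi_oracle
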