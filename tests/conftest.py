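import math

import pytest

import ionnet as inn
from ionnet.dataset import ELEMENTS
from ionnet.synthetic import BASELINE_MEANS, DEFAULT_CV


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default study design (seed fixed)."""
    return inn.generate_dataset(inn.default_config(), seed=1)


def make_plain_config(groups=("WT",), timepoints=(4.0,), n_replicates=6,
                      elements=ELEMENTS, planted=(), cv=DEFAULT_CV,
                      outlier_rate=0.0, shifts=None):
    """Minimal synthetic study: baseline means everywhere, optional planted
    correlations and multiplicative mean shifts {(group, element): factor}."""
    tp = {g: tuple(timepoints) for g in groups}
    shifts = shifts or {}
    means = {}
    for g in groups:
        for t in tp[g]:
            for e in elements:
                means[(g, t, e)] = BASELINE_MEANS.get(e, 1.0) * shifts.get((g, e), 1.0)
    return inn.SyntheticConfig(
        groups=tuple(groups), timepoints_by_group=tp, n_replicates=n_replicates,
        elements=tuple(elements), cell_means=means,
        cell_cv={e: cv for e in elements},
        planted_correlations=list(planted), outlier_rate=outlier_rate)


def make_signature_config(shift_sd=3.0):
    """Two groups where the treated group has Se elevated and Fe depressed
    by ``shift_sd`` log-scale sd at every time point."""
    f = math.exp(shift_sd * DEFAULT_CV)
    return make_plain_config(
        groups=("AD", "Se"), timepoints=(4., 6., 8., 10., 12.),
        shifts={("Se", "Se"): f, ("Se", "Fe"): 1 / f})


BLOCK_ELEMENTS = ("Zn", "Cu", "Fe", "V", "Pb", "Cd", "Bi", "Mn")
BLOCKS = [{"Zn", "Cu"}, {"Fe", "V"}, {"Pb", "Cd", "Bi"}]


def make_block_config():
    """Eight elements, three planted correlated blocks, Mn independent."""
    pairs = [("Zn", "Cu"), ("Fe", "V"), ("Pb", "Cd"), ("Pb", "Bi"), ("Cd", "Bi")]
    planted = [("WT", t, a, b, 0.85) for t in (4., 6., 8.) for a, b in pairs]
    return make_plain_config(timepoints=(4., 6., 8.), elements=BLOCK_ELEMENTS,
                             planted=planted)


def blocks_recovered(clusters, blocks=BLOCKS) -> bool:
    """Every block sits inside one flat cluster and no two blocks share one."""
    homes = []
    for b in blocks:
        home = next((i for i, c in enumerate(clusters) if b <= c), None)
        if home is None:
            return False
        homes.append(home)
    return len(set(homes)) == len(blocks)
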