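import numpy as np
import pytest

from threedpcr import EditingModel, TargetSequence, generate_target
from threedpcr.editing_sim import CONTEXTS


@pytest.fixture
def target_500() -> TargetSequence:
    return generate_target(500, 0.45, seed=11)


@pytest.fixture
def uniform_model() -> EditingModel:
    return EditingModel(rate=0.1,
                        context_weights={c: 0.25 for c in CONTEXTS},
                        strand_policy="plus_only")


def random_target(rng: np.random.Generator, length: int = 100,
                  gc: float | None = None) -> TargetSequence:
    gc = float(rng.uniform(0.25, 0.65)) if gc is None else gc
    return generate_target(length, gc, seed=int(rng.integers(2**31)))


def tpc_model(tpc_weight: float, **kw) -> EditingModel:
    other = (1.0 - tpc_weight) / 3.0
    return EditingModel(context_weights={"ApC": other, "CpC": other,
                                         "GpC": other, "TpC": tpc_weight},
                        **kw)
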