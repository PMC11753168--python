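"""actimotif: elastic motif clustering and digital biomarkers for actigraphy."""

from .curves import (
    DistanceWeights,
    FunctionalCurve,
    SRVFCurve,
    WarpingFunction,
    identity_warp,
    uniform_grid,
)
from .elastic import (
    align,
    amplitude_distance,
    amplitude_phase_distance,
    elastic_distance,
    phase_distance,
    srvf_transform,
    warp_curve,
)

__version__ = "0.1.0"


def __getattr__(name):
    # heavier submodule surfaces, loaded on demand
    import importlib

    if name in {"cluster", "biomarkers", "models", "preprocess", "simulate", "pipeline", "cli"}:
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
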