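"""Miniature metabolic networks for validation and method studies.

Each toy is small enough for the brute-force positional-isotopomer
simulator to serve as an exact oracle, yet exercises one structural
feature of the full muscle network: plain unimolecular transfer, a
branch point with a symmetric pool, and a condensation cycle with an
exchange-coupled observation pool (a miniature of the TCA cycle +
glutamate arrangement, with free parameters ``F_cycle`` and ``F_exch``
playing the roles of the cycle and exchange fluxes).
"""

from __future__ import annotations

from .isotopomer_model import MetabolicNetwork, network_from_dict

__all__ = ["toy_linear_chain", "toy_branched", "toy_condensation_cycle"]


def toy_linear_chain() -> MetabolicNetwork:
    """src → a → b → sink, two carbons, tracer on C1 of the source."""
    return network_from_dict(
        {
            "name": "toy-linear",
            "metabolites": [
                {"name": "src", "carbons": 2, "extracellular": True,
                 "enrichment": ["tracer", 0.0]},
                {"name": "a", "carbons": 2, "pool": 0.5},
                {"name": "b", "carbons": 2, "pool": 0.2},
                {"name": "sink", "carbons": 2, "extracellular": True},
            ],
            "parameters": {"F": 0.05},
            "reactions": [
                {"name": "uptake", "equation": "src (ab) -> a (ab)", "flux": "F"},
                {"name": "step", "equation": "a (ab) -> b (ab)", "flux": "F"},
                {"name": "efflux", "equation": "b (ab) -> sink (ab)", "flux": "F"},
            ],
        }
    )


def toy_branched() -> MetabolicNetwork:
    """A 3-carbon pool split into a 1-carbon and a symmetric 2-carbon branch."""
    return network_from_dict(
        {
            "name": "toy-branched",
            "metabolites": [
                {"name": "src", "carbons": 3, "extracellular": True,
                 "enrichment": ["tracer", 0.0, 0.3]},
                {"name": "a", "carbons": 3, "pool": 0.4},
                {"name": "b", "carbons": 1, "pool": 0.1},
                {"name": "c", "carbons": 2, "pool": 0.3, "symmetric": True},
                {"name": "sink1", "carbons": 1, "extracellular": True},
                {"name": "sink2", "carbons": 2, "extracellular": True},
            ],
            "parameters": {"F": 0.04},
            "reactions": [
                {"name": "uptake", "equation": "src (abc) -> a (abc)", "flux": "F"},
                {"name": "split", "equation": "a (abc) -> b (a) + c (cb)", "flux": "F"},
                {"name": "out1", "equation": "b (a) -> sink1 (a)", "flux": "F"},
                {"name": "out2", "equation": "c (ab) -> sink2 (ab)", "flux": "F"},
            ],
        }
    )


def toy_condensation_cycle() -> MetabolicNetwork:
    """1-carbon feed condensing onto a recycling 2-carbon pool, with an
    exchange-coupled observation pool.

    ``src + y → z`` (condensation, flux ``F_cycle``), ``z → y + waste``
    with a one-position carbon shift so label accumulates around the
    cycle, and ``y ↔ obs`` exchange at ``F_exch`` — structurally a
    miniature of acetyl-CoA + OAA → citrate → … with α-ketoglutarate ↔
    glutamate exchange, and used for fast two-parameter fitting studies.
    """
    return network_from_dict(
        {
            "name": "toy-cycle",
            "metabolites": [
                {"name": "src", "carbons": 1, "extracellular": True,
                 "enrichment": ["tracer"]},
                {"name": "y", "carbons": 2, "pool": 0.15},
                {"name": "z", "carbons": 3, "pool": 0.1},
                {"name": "obs", "carbons": 2, "pool": 0.8},
                {"name": "waste", "carbons": 1, "extracellular": True},
            ],
            "parameters": {"F_cycle": 0.05, "F_exch": 0.03},
            "reactions": [
                {"name": "condense", "equation": "src (a) + y (bc) -> z (abc)",
                 "flux": "F_cycle"},
                {"name": "split", "equation": "z (abc) -> y (ab) + waste (c)",
                 "flux": "F_cycle"},
                {"name": "exch_fwd", "equation": "y (ab) -> obs (ab)",
                 "flux": "F_exch"},
                {"name": "exch_rev", "equation": "obs (ab) -> y (ab)",
                 "flux": "F_exch"},
            ],
        }
    )
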