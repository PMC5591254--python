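"""cellpath: single-cell pathway activity, WGA coverage QC, driver screening.

A Bayesian-network model infers transcription-complex activity (e.g.
the canonical Wnt program) from per-gene expression evidence; coverage
QC summarizes whole-genome-amplification uniformity via Lorenz curves
and Gini coefficients; a driver-mutation panel screen genotypes the
same cells with breadth gating; a synthetic-data generator makes the
whole analysis testable end to end.
"""

from importlib import resources

from . import calibration, coverage_qc, pathway_model, pipeline, synthetic_data, variant_panel

__all__ = [
    "calibration",
    "coverage_qc",
    "pathway_model",
    "pipeline",
    "synthetic_data",
    "variant_panel",
    "bundled_wnt_panel",
    "bundled_driver_panel",
]

__version__ = "0.1.0"


def bundled_wnt_panel() -> str:
    """Path to the bundled 34-gene Wnt target panel (synthetic stand-in)."""
    return str(resources.files(__name__) / "data" / "wnt_target_panel_synthetic.tsv")


def bundled_driver_panel() -> str:
    """Path to the bundled LS174T/RKO driver-mutation panel."""
    return str(resources.files(__name__) / "data" / "ls174t_driver_panel.tsv")
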