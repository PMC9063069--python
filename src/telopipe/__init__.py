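"""telopipe: leukocyte telomere length (T/S ratio) analysis pipeline.

qPCR standard-curve quantification with Dixon's Q triplicate QC,
control-DNA batch adjustment and duplicate concordance, longitudinal
pregnancy-cohort statistics, and a multivariate perceived-stress screen —
plus a synthetic plate/cohort generator with planted ground truth for
end-to-end testing.
"""

__version__ = "0.1.0"

from . import batch, cohort, quant, screen  # noqa: F401

__all__ = ["batch", "cohort", "quant", "screen", "synth", "pipeline", "__version__"]


def __getattr__(name):
    # synth and pipeline import heavier dependencies; load lazily
    if name in ("synth", "pipeline"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
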