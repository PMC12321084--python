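"""Exception types raised by the simulator."""

from __future__ import annotations


class DimensionMismatchError(ValueError):
    """Strategy, nutrient, or community dimensions are inconsistent."""


class NondepletionError(RuntimeError):
    """A batch hit ``max_time`` before the nutrients were depleted.

    Carries the partial within-batch timecourse in :attr:`timecourse` so the
    caller can diagnose an ill-posed configuration (for instance, a nutrient
    no species can consume).
    """

    def __init__(self, message: str, timecourse=None):
        super().__init__(message)
        self.timecourse = timecourse


class DegenerateCommunityError(ValueError):
    """The community has zero total biomass and cannot be diluted."""


class UndefinedSenseError(ValueError):
    """Both nutrient concentrations are zero; the relative difference is undefined."""


class StalledBatchError(RuntimeError):
    """All remaining cells have zero uptake for the remaining nutrient.

    Carries the partial :attr:`population` at the moment the batch stalled;
    the leftover nutrient is discarded.
    """

    def __init__(self, message: str, population=None):
        super().__init__(message)
        self.population = population


class InfeasibleSamplingError(ValueError):
    """The end-of-batch population is smaller than the requested inoculum."""


class NumericalFailureError(RuntimeError):
    """The Fokker-Planck stepper underflowed its step size."""
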