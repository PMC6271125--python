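"""Hold-out validation: predict the withheld sample from the fitted parameters.

One late-time sample per replicate is excluded from fitting; after the
two-loop fit, the model curve is evaluated at that time and compared with the
observation.  The discrepancy is signed as ``100 * (predicted - observed) /
observed``, so over-prediction — the signature of a run that had not reached
equilibrium by its final sample — is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kinetics import net_conc

__all__ = ["ValidationReport", "validate_holdout"]


@dataclass(frozen=True)
class ValidationReport:
    """Per-replicate hold-out predictions and percent discrepancies."""

    compound: str
    condition: str
    frame: pd.DataFrame  # replicate, t_holdout, observed, predicted, discrepancy_percent

    @property
    def max_abs_discrepancy(self) -> float:
        """Largest |percent discrepancy| across replicates."""
        return float(self.frame["discrepancy_percent"].abs().max())

    @property
    def mean_discrepancy(self) -> float:
        return float(self.frame["discrepancy_percent"].mean())

    def to_csv(self, path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "compound", self.compound)
        out.to_csv(path, index=False)
        return path


def validate_holdout(results) -> ValidationReport:
    """Predict every replicate's withheld sample from its own fitted parameters.

    Predictions and observations are on the normalized scale (the scale the
    fit ran on); parameters were fitted *without* the held-out sample.

    Raises
    ------
    ValueError
        If no hold-out point was selected on the model.
    """
    model = results.model
    rows = []
    for fit in results.replicate_fits:
        prof = next(
            p for p in model.norm_data.profiles if p.replicate_id == fit.replicate_id
        )
        if prof.holdout is None:
            raise ValueError(
                f"{model.data.label} rep {fit.replicate_id}: no hold-out point; "
                "construct the model with validation_time="
            )
        t_h, observed = prof.holdout
        predicted = float(net_conc(fit.params, t_h))
        rows.append(
            {
                "replicate": fit.replicate_id,
                "t_holdout": t_h,
                "observed": observed,
                "predicted": predicted,
                "discrepancy_percent": 100.0 * (predicted - observed) / observed,
            }
        )
    return ValidationReport(
        compound=model.data.compound,
        condition=model.data.condition,
        frame=pd.DataFrame(rows),
    )
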