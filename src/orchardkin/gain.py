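"""Realized breeding gain under observed background pollen contamination.

Deployment tools quote an expected gain for an orchard under an assumed BPC
level.  Contaminating pollen carries no breeding gain, so gain scales with
the fraction of non-contaminating pollination events: the contamination-free
gain is G0 = expected / (1 - assumed_bpc) and the gain realized at the
observed contamination is G0 * (1 - observed_bpc).

An alternative reading, in which a contaminated seed retains the maternal
half of the gain (factor 1 - b/2), is available via ``half_genome=True`` but
is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class GainSpec:
    """Expected-gain declaration for one orchard crop."""

    orchard_id: str
    expected_gain: float  # percent, under assumed_bpc
    assumed_bpc: float  # fraction in [0, 1)
    observed_bpc: float  # fraction in [0, 1)

    def __post_init__(self) -> None:
        if self.expected_gain < 0:
            raise ValueError("expected_gain must be >= 0")
        for name in ("assumed_bpc", "observed_bpc"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class GainResult:
    orchard_id: str
    contamination_free_gain: float
    realized_gain: float
    delta_vs_expected: float

    @property
    def realized_rounded(self) -> float:
        return round(self.realized_gain, 1)


def realized_gain(spec: GainSpec, half_genome: bool = False) -> GainResult:
    """Gain realized under the observed BPC, full precision internally.

    ``half_genome`` applies the (1 - b/2) variant in which contaminated
    seeds keep the maternal gain contribution.
    """
    factor = 0.5 if half_genome else 1.0
    g0 = spec.expected_gain / (1.0 - factor * spec.assumed_bpc)
    realized = g0 * (1.0 - factor * spec.observed_bpc)
    return GainResult(
        orchard_id=spec.orchard_id,
        contamination_free_gain=g0,
        realized_gain=realized,
        delta_vs_expected=realized - spec.expected_gain,
    )


def gain_table(
    specs: list[GainSpec],
    observed_bpc: dict[str, float] | None = None,
    half_genome: bool = False,
) -> pd.DataFrame:
    """One row per crop: expected gain, observed BPC, realized gain.

    ``observed_bpc`` overrides each spec's observed value by orchard id
    (joins measured contamination from the parentage stage); percentages
    are rendered to one decimal.
    """
    import warnings

    rows = []
    for spec in specs:
        if observed_bpc is not None:
            if spec.orchard_id not in observed_bpc:
                warnings.warn(f"no observed BPC for {spec.orchard_id}; row omitted", stacklevel=2)
                continue
            spec = GainSpec(
                spec.orchard_id, spec.expected_gain, spec.assumed_bpc, observed_bpc[spec.orchard_id]
            )
        res = realized_gain(spec, half_genome=half_genome)
        rows.append(
            {
                "orchard_id": spec.orchard_id,
                "expected_gain": spec.expected_gain,
                "assumed_bpc_pct": round(100.0 * spec.assumed_bpc, 1),
                "observed_bpc_pct": round(100.0 * spec.observed_bpc, 1),
                "realized_gain": res.realized_rounded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["orchard_id", "expected_gain", "assumed_bpc_pct", "observed_bpc_pct", "realized_gain"],
    )
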