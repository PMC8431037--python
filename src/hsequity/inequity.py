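"""Need-vs-inequity partition of a decomposed utilization gap.

Part of a gap in health-service utilization is legitimate: differences in
*need* (age, gender, health status) are expected to produce differences in
use. The need-caused difference is the sum of the decomposition
contributions of the need blocks; the remainder of the total gap — the part
not attributable to need — is the horizontal-inequity index:

    inequity_index = total_gap − need_difference.

On the percent scale the two shares add to 100% of the gap.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .fairlie import DecompositionResult

#: default need blocks: demographic and health-status covariates
DEFAULT_NEED_BLOCKS = ("age_group", "gender", "sah")

__all__ = [
    "NeedPartition",
    "InequityResult",
    "need_difference",
    "inequity_index",
    "inequity_from_decomposition",
    "DEFAULT_NEED_BLOCKS",
]


@dataclass(frozen=True)
class NeedPartition:
    """Split of the decomposed covariate blocks into need vs other."""

    need_blocks: tuple[str, ...] = DEFAULT_NEED_BLOCKS

    def other_blocks(self, all_blocks: Sequence[str]) -> tuple[str, ...]:
        return tuple(b for b in all_blocks if b not in self.need_blocks)

    def validate(self, all_blocks: Sequence[str]) -> None:
        unknown = [b for b in self.need_blocks if b not in all_blocks]
        if unknown:
            raise KeyError(
                f"need blocks {unknown} are not among the decomposed blocks "
                f"{list(all_blocks)}"
            )


@dataclass
class InequityResult:
    need_difference: float
    need_percent: float
    inequity_index: float
    inequity_percent: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.need_difference, self.inequity_index],
                "pct_of_gap": [self.need_percent, self.inequity_percent],
            },
            index=pd.Index(
                ["difference_caused_by_need", "inequity_index"], name="term"
            ),
        )


def need_difference(
    contributions: DecompositionResult | Mapping[str, float],
    partition: NeedPartition | Sequence[str] = NeedPartition(),
) -> float:
    """Sum of the (probability- or percent-scale) contributions of the need blocks.

    Accepts a :class:`DecompositionResult` (its probability-scale
    contributions are summed) or any ``{block: contribution}`` mapping, e.g.
    percent contributions from a published table. An empty partition gives 0.
    """
    if not isinstance(partition, NeedPartition):
        partition = NeedPartition(tuple(partition))
    if isinstance(contributions, DecompositionResult):
        values = contributions.contributions
    else:
        values = pd.Series(dict(contributions), dtype=float)
    partition.validate(list(values.index))
    if not partition.need_blocks:
        return 0.0
    return float(values.loc[list(partition.need_blocks)].sum())


def inequity_index(total_gap: float, need_diff: float) -> float:
    """Inequitable share of the gap: total gap minus the need-caused part."""
    return total_gap - need_diff


def inequity_from_decomposition(
    decomp: DecompositionResult,
    partition: NeedPartition | Sequence[str] = NeedPartition(),
) -> InequityResult:
    """Full partition of a decomposition into need and inequity components."""
    need = need_difference(decomp, partition)
    inequity = inequity_index(decomp.total_gap, need)
    if decomp.total_gap != 0:
        need_pct = 100.0 * need / decomp.total_gap
        ineq_pct = 100.0 - need_pct
    else:
        need_pct = ineq_pct = float("nan")
    return InequityResult(
        need_difference=need,
        need_percent=need_pct,
        inequity_index=inequity,
        inequity_percent=ineq_pct,
    )
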