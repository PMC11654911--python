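"""Decision-vector <-> channel-count encoding and channel-change reports.

A candidate architecture is a real vector x in [-0.5, 0.5]^43, one coordinate
per tunable convolution layer (31 down-sampling DSCL slots followed by 12
up-sampling USCL slots; depthwise convolutions are not tunable).  Decoding
applies l' = l - floor(l * x) per layer, so x = -0.5 yields the maximum
increase (+l/2) and x = 0.5 roughly halves the layer.

The packaged reference plan carries the published base (UConvNeXt) and
optimized (AAUConvNeXt) channel counts for all 43 slots; the reduction-ratio
report reproduces its printed percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChannelPlan",
    "ReductionReport",
    "N_SLOTS",
    "decode_channels",
    "reduction_ratio",
    "summarize_plan",
    "reference_base_plan",
    "reference_optimized_plan",
    "load_plan_csv",
]

N_SLOTS = 43
_N_DSCL = 31
_N_USCL = 12


@dataclass(frozen=True)
class ChannelPlan:
    """Ordered per-layer (base, optimized) channel counts for the 43 slots."""

    layer_ids: tuple[str, ...]
    base: tuple[int, ...]
    optimized: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.layer_ids)
        if not (len(self.base) == len(self.optimized) == n):
            raise ValueError("layer_ids, base and optimized must have equal length")
        if any(b < 1 for b in self.base) or any(o < 1 for o in self.optimized):
            raise ValueError("channel counts must be positive")

    def __len__(self) -> int:
        return len(self.layer_ids)

    @property
    def entries(self) -> list[tuple[str, int, int]]:
        return list(zip(self.layer_ids, self.base, self.optimized))

    def identity(self) -> "ChannelPlan":
        """A plan whose optimized counts equal its base counts."""
        return ChannelPlan(self.layer_ids, self.base, self.base)

    def scaled(self, divisor: int, minimum: int = 4) -> "ChannelPlan":
        """Shrink every channel count by an integer divisor (desk-scale runs)."""
        base = tuple(max(minimum, b // divisor) for b in self.base)
        opt = tuple(max(minimum, o // divisor) for o in self.optimized)
        return ChannelPlan(self.layer_ids, base, opt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"layer_id": self.layer_ids, "base": self.base, "optimized": self.optimized}
        )


@dataclass(frozen=True)
class ReductionReport:
    """Per-layer reduction ratios plus the increase/decrease tally."""

    frame: pd.DataFrame  # columns: layer_id, base, optimized, reduction_ratio_percent
    n_increased: int
    n_decreased: int
    n_unchanged: int

    def to_text(self) -> str:
        lines = [f"{'layer':<10}{'base':>8}{'optimized':>11}{'reduction':>11}"]
        for row in self.frame.itertuples(index=False):
            lines.append(
                f"{row.layer_id:<10}{row.base:>8}{row.optimized:>11}"
                f"{row.reduction_ratio_percent:>10.2f}%"
            )
        lines.append(
            f"increased: {self.n_increased}  decreased: {self.n_decreased}  "
            f"unchanged: {self.n_unchanged}"
        )
        return "\n".join(lines)


def default_layer_ids() -> tuple[str, ...]:
    return tuple(
        [f"DSCL {i:02d}" for i in range(1, _N_DSCL + 1)]
        + [f"USCL {i:02d}" for i in range(1, _N_USCL + 1)]
    )


def decode_channels(x: np.ndarray, base_plan: ChannelPlan) -> ChannelPlan:
    """Apply l' = l - floor(l * x) slot-wise; floor is toward minus infinity.

    The floor-toward--inf convention is what makes x = -0.5 on a 64-channel
    layer give 64 - floor(-32) = 96 (a 50% increase).  Decoded counts are
    clamped to at least 1 channel.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(base_plan),):
        raise ValueError(f"decision vector must have length {len(base_plan)}, got {x.shape}")
    if np.any(x < -0.5) or np.any(x > 0.5):
        raise ValueError("decision variables must lie in [-0.5, 0.5]; clip before decoding")
    optimized = tuple(
        max(1, b - math.floor(b * xi)) for b, xi in zip(base_plan.base, x)
    )
    return ChannelPlan(base_plan.layer_ids, base_plan.base, optimized)


def reduction_ratio(base: int, optimized: int) -> float:
    """100*(base - optimized)/base, rounded half-up to 2 decimals (negative = increase)."""
    if base < 1:
        raise ValueError("base channel count must be at least 1")
    ratio = Decimal(100 * (base - optimized)) / Decimal(base)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_plan(plan: ChannelPlan) -> ReductionReport:
    """Per-row reduction ratios plus counts of increased/decreased/unchanged layers."""
    rows = []
    n_inc = n_dec = n_same = 0
    for layer_id, base, opt in plan.entries:
        rows.append(
            {
                "layer_id": layer_id,
                "base": base,
                "optimized": opt,
                "reduction_ratio_percent": reduction_ratio(base, opt),
            }
        )
        if opt > base:
            n_inc += 1
        elif opt < base:
            n_dec += 1
        else:
            n_same += 1
    return ReductionReport(
        frame=pd.DataFrame(rows),
        n_increased=n_inc,
        n_decreased=n_dec,
        n_unchanged=n_same,
    )


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("lodgeseg.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_plan_csv(path_or_frame) -> ChannelPlan:
    """Read a plan from a CSV with columns layer_id, base, optimized."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame)
    missing = {"layer_id", "base", "optimized"} - set(df.columns)
    if missing:
        raise ValueError(f"plan CSV missing columns: {sorted(missing)}")
    return ChannelPlan(
        tuple(df["layer_id"].astype(str)),
        tuple(int(v) for v in df["base"]),
        tuple(int(v) for v in df["optimized"]),
    )


def reference_plan() -> ChannelPlan:
    """The packaged 43-slot reference plan (published base and optimized counts)."""
    return load_plan_csv(_packaged_csv("reference_channel_plan.csv"))


def reference_base_plan() -> ChannelPlan:
    """The baseline UConvNeXt channel plan (optimized = base)."""
    return reference_plan().identity()


def reference_optimized_plan() -> ChannelPlan:
    """The published AFOA-APOM-optimized (AAUConvNeXt) channel plan."""
    return reference_plan()


def reference_reduction_ratios() -> pd.DataFrame:
    """The published per-layer reduction ratios (regression fixture)."""
    return _packaged_csv("reference_reduction_ratios.csv")


def ablation_table() -> pd.DataFrame:
    """The published ablation metrics block (PA/MPA/mIoU/params/FLOPs per model)."""
    return _packaged_csv("ablation_metrics.csv")


def ablation_summary() -> dict[str, float]:
    """Arithmetic derived from the ablation table: accuracy gains and cost drops."""
    df = ablation_table().set_index("model")
    base = df.loc["UConvNeXt"]
    afoa = df.loc["AUConvNeXt"]
    full = df.loc["AAUConvNeXt"]

    def pct_drop(a: float, b: float) -> float:
        return float(
            (Decimal(100) * (Decimal(str(a)) - Decimal(str(b))) / Decimal(str(a))).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )

    return {
        "miou_gain_pct": float(
            Decimal(str(full["miou_pct"])) - Decimal(str(base["miou_pct"]))
        ),
        "pa_gain_pct": float(Decimal(str(full["pa_pct"])) - Decimal(str(base["pa_pct"]))),
        "flops_drop_afoa_pct": pct_drop(base["flops_g"], afoa["flops_g"]),
        "flops_drop_full_pct": pct_drop(base["flops_g"], full["flops_g"]),
        "params_drop_afoa_pct": pct_drop(base["params_m"], afoa["params_m"]),
        "params_drop_full_pct": pct_drop(base["params_m"], full["params_m"]),
    }
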