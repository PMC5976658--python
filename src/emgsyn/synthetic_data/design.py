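"""Point-to-point task design: 9 targets, 72 ordered movements, 10 task parameters.

Nine targets sit on three vertical bars at three heights.  Target ids run
T1..T3 along the top row, T4..T6 along the middle row and T7..T9 along the
bottom row; within a row targets are ordered right-to-left, so bar 1 is on
the participant's right and bar 3 on the participant's left (T1 -> T3 is a
leftward movement).  Every ordered pair of distinct targets is a movement,
giving 9 x 8 = 72 movements, each characterized by 10 discrete parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Height levels, top to bottom.
HEIGHTS = ("T", "M", "B")

#: The 10 discrete task parameters describing a movement.
TASK_PARAMETERS = (
    "start_target",
    "start_bar",
    "start_height",
    "direction",
    "horizontal_direction",
    "vertical_direction",
    "end_bar",
    "end_height",
    "end_target",
    "movement_id",
)

#: Parameters describing the temporal structure of the task (movement
#: beginning, transient phase, movement end).
TEMPORAL_PARAMETERS = ("start_target", "direction", "end_target")

#: Parameters describing the spatial (horizontal/vertical) structure.
SPATIAL_PARAMETERS = (
    "start_bar",
    "horizontal_direction",
    "end_bar",
    "start_height",
    "vertical_direction",
    "end_height",
)


@dataclass(frozen=True)
class Target:
    """One pointing target: id 1..9, bar 1..3 and height level."""

    target_id: int
    bar: int
    height: str

    @property
    def height_rank(self) -> int:
        """0 for top, 1 for middle, 2 for bottom."""
        return HEIGHTS.index(self.height)


def _make_target(target_id: int) -> Target:
    if not 1 <= target_id <= 9:
        raise ValueError(f"target id must be in 1..9, got {target_id}")
    row = (target_id - 1) // 3
    bar = (target_id - 1) % 3 + 1
    return Target(target_id=target_id, bar=bar, height=HEIGHTS[row])


@dataclass(frozen=True)
class TaskDesign:
    """The full 9-target / 72-movement design with its parameter table."""

    targets: tuple[Target, ...]
    movements: tuple[tuple[int, int], ...]
    parameter_table: pd.DataFrame = field(repr=False)

    def target(self, target_id: int) -> Target:
        return self.targets[target_id - 1]

    def movement_record(self, movement_id: int) -> dict:
        """Parameter record of one movement as a plain dict."""
        row = self.parameter_table.loc[
            self.parameter_table["movement_id"] == movement_id
        ]
        if len(row) != 1:
            raise KeyError(f"unknown movement id {movement_id}")
        return row.iloc[0].to_dict()

    def n_classes(self, parameter: str) -> int:
        """Number of distinct values a task parameter takes in this design."""
        if parameter not in TASK_PARAMETERS:
            raise KeyError(f"unknown task parameter {parameter!r}")
        return int(self.parameter_table[parameter].nunique())


def derive_task_parameters(
    start_target: int, end_target: int, design: "TaskDesign | None" = None
) -> dict:
    """Derive the 10-parameter record of one movement from its target pair.

    Horizontal direction is L when the end bar is higher-numbered than the
    start bar (bars are numbered right-to-left), R when lower, S when equal.
    Vertical direction is D when the end target sits lower, U when higher,
    S when at the same height.  The combined direction concatenates the
    vertical and horizontal components ("UL", "DS", ...).
    """
    if start_target == end_target:
        raise ValueError(
            f"start and end targets must differ (got target {start_target} twice)"
        )
    if design is not None:
        start, end = design.target(start_target), design.target(end_target)
    else:
        start, end = _make_target(start_target), _make_target(end_target)

    if end.bar > start.bar:
        horizontal = "L"
    elif end.bar < start.bar:
        horizontal = "R"
    else:
        horizontal = "S"
    if end.height_rank > start.height_rank:
        vertical = "D"
    elif end.height_rank < start.height_rank:
        vertical = "U"
    else:
        vertical = "S"

    return {
        "start_target": start.target_id,
        "start_bar": start.bar,
        "start_height": start.height,
        "direction": vertical + horizontal,
        "horizontal_direction": horizontal,
        "vertical_direction": vertical,
        "end_bar": end.bar,
        "end_height": end.height,
        "end_target": end.target_id,
    }


def build_task_design() -> TaskDesign:
    """Build the full design: all 72 ordered pairs of distinct targets.

    Deterministic; movement ids 1..72 follow (start_target, end_target)
    lexicographic order.
    """
    targets = tuple(_make_target(t) for t in range(1, 10))
    movements = []
    records = []
    movement_id = 0
    for start in range(1, 10):
        for end in range(1, 10):
            if start == end:
                continue
            movement_id += 1
            rec = derive_task_parameters(start, end)
            rec["movement_id"] = movement_id
            movements.append((start, end))
            records.append(rec)
    table = pd.DataFrame.from_records(records, columns=list(TASK_PARAMETERS))
    return TaskDesign(
        targets=targets, movements=tuple(movements), parameter_table=table
    )
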