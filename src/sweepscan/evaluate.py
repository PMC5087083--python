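"""Recovery metrics of called regions against a simulator truth set."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


@dataclass
class Recovery:
    sensitivity: float          # fraction of truth sweeps hit by >= 1 called region
    fdp: float                  # fraction of called regions hitting no truth sweep
    n_truth: int
    n_called: int
    n_truth_hit: int
    n_false_regions: int


def recovery_metrics(
    called: dict[str, pd.DataFrame] | pd.DataFrame,
    truth: pd.DataFrame,
    per_population: bool = True,
) -> Recovery:
    """Compare called regions with planted sweeps by >= 1 bp overlap.

    ``called`` is either one region table or the dict from
    :func:`sweepscan.regions.call_regions` (tables are concatenated). When
    ``per_population`` is set, a truth sweep only counts as recovered by a
    region called for its target population (or for "both"); false-positive
    status of a region is judged against all truth intervals regardless.
    """
    if isinstance(called, dict):
        frames = [df for df in called.values() if len(df)]
        called = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "start", "end", "population"])
        )
    n_truth = len(truth)
    n_called = len(called)

    hit = 0
    for t in truth.itertuples():
        for r in called.itertuples():
            if r.chrom != t.chrom or not _overlaps(t.start, t.end, r.start, r.end):
                continue
            pop = getattr(r, "population", "both")
            if per_population and pop not in ("both", t.target_pop):
                continue
            hit += 1
            break
    false = 0
    for r in called.itertuples():
        if not any(
            r.chrom == t.chrom and _overlaps(t.start, t.end, r.start, r.end)
            for t in truth.itertuples()
        ):
            false += 1
    return Recovery(
        sensitivity=hit / n_truth if n_truth else float("nan"),
        fdp=false / n_called if n_called else 0.0,
        n_truth=n_truth,
        n_called=n_called,
        n_truth_hit=hit,
        n_false_regions=false,
    )
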