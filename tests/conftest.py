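"""Shared fixtures: small simulated movies and independent oracles.

The rendered movie fixture is session-scoped because rendering dominates
test runtime; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from tirfkin.imaging import ImageStack
from tirfkin.schedule import AcquisitionSchedule
from tirfkin.simulate import (
    DriftSpec,
    SimulationParams,
    SpeciesKinetics,
    render_movie,
    simulate_pulse_trains,
)


def brute_force_pulse_scan(
    on: list[bool], min_on_frames: int, max_gap_frames: int
) -> list[tuple[int, int, bool, bool]]:
    """Independent run-length state machine.

    Returns (first_frame, last_frame, censored, present_at_start) per pulse,
    bridging OFF gaps of at most ``max_gap_frames`` frames and discarding
    runs spanning fewer than ``min_on_frames`` frames.
    """
    n = len(on)
    out = []
    i = 0
    while i < n:
        if not on[i]:
            i += 1
            continue
        start = i
        last = i
        gap = 0
        j = i + 1
        while j < n:
            if on[j]:
                last = j
                gap = 0
            else:
                gap += 1
                if gap > max_gap_frames:
                    break
            j += 1
        if last - start + 1 >= min_on_frames:
            out.append((start, last, last == n - 1, start == 0))
        i = max(last + 1, j)
    return out


@pytest.fixture(scope="session")
def two_channel_schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule(2700.0, {"647": 60.0, "488": 5.0})


@pytest.fixture(scope="session")
def small_movie(two_channel_schedule):
    """150-spot, 256 px field, 45-min movie with 0.02 px/frame linear drift."""
    params = SimulationParams(
        n_spots=150,
        field_size=(256, 256),
        kinetics={"488": SpeciesKinetics(k_on=1.0, k_off=30.0, k_bleach=2.0)},
        drift=DriftSpec(velocity=(0.004, 0.002)),  # 10.8 / 5.4 px over 2700 s
        seed=2,
    )
    truth = simulate_pulse_trains(params, two_channel_schedule)
    stacks = render_movie(truth, params, two_channel_schedule)
    image_stacks = {
        ch: ImageStack(ch, arr, two_channel_schedule.frame_times(ch), params.pixel_size)
        for ch, arr in stacks.items()
    }
    return params, truth, image_stacks


@pytest.fixture(scope="session")
def noise_free_single_spot(two_channel_schedule):
    """One always-ON spot, no noise, no drift: closed-form PSF oracle."""
    params = SimulationParams(
        n_spots=1,
        field_size=(64, 64),
        kinetics={"488": SpeciesKinetics(k_on=0.0, k_off=0.0, k_bleach=0.0)},
        noise_model="none",
        initial_occupancy=1.0,
        seed=5,
    )
    truth = simulate_pulse_trains(params, two_channel_schedule)
    stacks = render_movie(truth, params, two_channel_schedule)
    return params, truth, stacks
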