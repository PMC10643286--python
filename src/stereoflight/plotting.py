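"""Publication-style figures: flight time courses and polar segment plots."""

from __future__ import annotations

import numpy as np

from .circular import MMRResult
from .kinematics import KinematicsSeries
from .segmentation import FlightPhases, FlightSegment

PHASE_COLORS = {
    "approach": "tab:orange",
    "descent": "tab:red",
    "landing_strict": "tab:red",
    "landing": "tab:red",
    "departure": "tab:purple",
}


def plot_flight_timecourse(kin: KinematicsSeries, phases: FlightPhases | None = None, axes=None):
    """Altitude and vertical velocity vs time, with phase windows shaded."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax_alt, ax_vz = axes
    ax_alt.plot(kin.t, kin.altitude, "k-", lw=1)
    ax_alt.set_ylabel("altitude (mm)")
    ax_vz.plot(kin.t, kin.vertical_velocity, "-", color="grey", lw=1)
    ax_vz.set_ylabel("vertical velocity (m/s)")
    ax_vz.set_xlabel("time relative to water contact (s)")
    if phases is not None:
        for name in ("descent", "landing_strict"):
            i0, i1 = phases.interval(name)
            for ax in (ax_alt, ax_vz):
                ax.axvspan(kin.t[i0], kin.t[min(i1, len(kin) - 1)], alpha=0.15,
                           color=PHASE_COLORS[name])
    return axes


def plot_polar_segments(
    segments: list[FlightSegment],
    phase: str,
    mmr: MMRResult | None = None,
    significance_r: float | None = None,
    ax=None,
):
    """Polar plot of segment mean directions, vector length = directedness.

    The overlaid black vector shows the MMR mean angle with magnitude R*; the
    dashed circle the significance limit for R* when supplied.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    segs = [s for s in segments if s.phase == phase]
    if segs:
        rmax = max(s.r for s in segs)
        for s in segs:
            theta = np.radians(s.mean_direction)
            ax.plot([theta, theta], [0.0, s.r / rmax], color=PHASE_COLORS.get(phase, "tab:blue"),
                    lw=1, alpha=0.7)
    if mmr is not None:
        theta = np.radians(mmr.mean_angle)
        ax.annotate(
            "",
            xy=(theta, mmr.r_star),
            xytext=(0.0, 0.0),
            arrowprops={"arrowstyle": "-|>", "color": "black", "lw": 2},
        )
        ax.set_title(f"{phase}: R*={mmr.r_star:.2f}, p={mmr.p_value:.3f}", fontsize=9)
    if significance_r is not None:
        ax.plot(np.linspace(0, 2 * np.pi, 200), np.full(200, significance_r), "k--", lw=0.8)
    ax.set_theta_zero_location("E")
    return ax


def plot_mean_curves(curves, axes=None):
    """Cohort mean altitude / horizontal speed / vertical velocity vs time."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
    for ax, (label, y) in zip(
        axes,
        (
            ("altitude (mm)", curves.altitude),
            ("horizontal speed (m/s)", curves.horizontal_speed),
            ("vertical velocity (m/s)", curves.vertical_velocity),
        ),
    ):
        ax.plot(curves.t, y, "k--", lw=1.5)
        ax.axvline(0.0, color="grey", lw=0.5)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("time relative to water contact (s)")
    return axes
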