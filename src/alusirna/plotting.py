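"""Optional matplotlib views of the profiler outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

from .profiling import ConsensusProfile, DifferentialProfile, LengthDistribution

__all__ = [
    "plot_length_distribution",
    "plot_consensus_profile",
    "plot_differential_profile",
]


def plot_length_distribution(ld: LengthDistribution, ax=None):
    """Sense/antisense Alu read CPM per length (paired bars)."""
    if ax is None:
        _, ax = plt.subplots()
    w = 0.4
    ax.bar(ld.lengths - w / 2, ld.sense_cpm, width=w, label="sense")
    ax.bar(ld.lengths + w / 2, ld.antisense_cpm, width=w, label="antisense")
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("counts per million reads")
    ax.legend()
    return ax


def plot_consensus_profile(profile: ConsensusProfile, ax=None):
    """5'-start counts along a consensus; antisense drawn downward."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.sense, label="sense", drawstyle="steps-mid")
    ax.plot(-profile.antisense, label="antisense", drawstyle="steps-mid")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel(f"position on {profile.consensus_id} (nt)")
    ax.set_ylabel("5' start count")
    ax.legend()
    return ax


def plot_differential_profile(dp: DifferentialProfile, ax=None):
    """Knockdown-minus-control normalized read difference per length."""
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(dp.lengths, dp.delta)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("siRNA length (nt)")
    ax.set_ylabel("normalized read difference")
    return ax
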