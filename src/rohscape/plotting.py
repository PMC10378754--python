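"""Optional Manhattan-style plotting of per-SNP ROH incidence.

Requires matplotlib; everything the plots show is also written as TSV by the
pipeline, so plotting is never on the analysis path.
"""

from __future__ import annotations

from .islands import IncidenceTrack

__all__ = ["plot_incidence"]


def plot_incidence(track: IncidenceTrack, threshold: float | None = None, ax=None):
    """Manhattan plot of standardized in-ROH incidence with the island
    threshold line; chromosomes alternate in shade."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    if track.z is None:
        raise ValueError("incidence track has zero variance; nothing to plot")
    x = 0
    ticks, labels = [], []
    for k, (chrom, sl) in enumerate(track.markers.chrom_slices().items()):
        n = sl.stop - sl.start
        ax.scatter(
            range(x, x + n),
            track.z[sl],
            s=2,
            color="steelblue" if k % 2 == 0 else "darkorange",
            rasterized=True,
        )
        ticks.append(x + n // 2)
        labels.append(chrom)
        x += n
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("standardized incidence (z)")
    if track.group:
        ax.set_title(track.group)
    return ax
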