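"""Simple diagnostic plots (optional outputs of the pipeline)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_evi_trajectory(station_year_evi, stations, path):
    """Station-year EVI against years since reclamation for reclaimed
    stations, with natural stations as a reference band."""
    merged = station_year_evi.merge(stations, on="station_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    rec = merged[merged["station_class"] == "reclaimed"].copy()
    rec["age"] = rec["year"] - rec["reclamation_start_year"]
    for sid, grp in rec.groupby("station_id"):
        ax.plot(grp["age"], grp["evi"], "o-", label=sid, alpha=0.8)
    nat = merged[merged["station_class"] == "natural"]["evi"]
    if not nat.empty:
        ax.axhspan(nat.quantile(0.25), nat.quantile(0.75), color="green",
                   alpha=0.15, label="natural IQR")
    ax.set_xlabel("years since reclamation")
    ax.set_ylabel("June EVI")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_species_coefficients(posterior, path):
    """Forest plot of species EVI coefficients sorted by posterior mean."""
    beta = posterior.draws["beta"].reshape(-1,
                                           len(posterior.species_codes))
    means = beta.mean(axis=0)
    order = means.argsort()
    lo = [float(x) for x in
          [sorted(beta[:, j])[int(0.025 * beta.shape[0])] for j in order]]
    hi = [float(x) for x in
          [sorted(beta[:, j])[int(0.975 * beta.shape[0]) - 1] for j in order]]
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(order) + 1.5))
    ys = range(len(order))
    ax.hlines(ys, lo, hi, color="gray")
    ax.plot(means[order], ys, "ko", ms=3)
    ax.axvline(0, color="red", lw=0.8, ls="--")
    ax.set_yticks(list(ys))
    ax.set_yticklabels([posterior.species_codes[j] for j in order],
                       fontsize=6)
    ax.set_xlabel("EVI coefficient (beta)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
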