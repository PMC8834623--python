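"""Per-patient monitoring plots: VAF, cfDNA and CEA tracks over time."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .monitoring import PatientTimeline

__all__ = ["plot_timeline"]

_EVENT_STYLE = {
    "surgery": ("black", "-"),
    "chemo_start": ("tab:blue", "--"),
    "chemo_end": ("tab:blue", ":"),
    "recurrence_clinical": ("tab:red", "-"),
    "metastasis_confirmed": ("tab:red", "--"),
    "remission": ("tab:green", "--"),
    "progression": ("tab:orange", "--"),
}


def plot_timeline(timeline: PatientTimeline, path: str | Path) -> None:
    """Three stacked tracks (ctDNA VAF, cfDNA, CEA) with event markers."""
    days = [s.day for s in timeline.samples]
    vaf = [s.call.vaf for s in timeline.samples]
    cf = [s.panel.cfdna_conc if s.panel else float("nan") for s in timeline.samples]
    cea = [s.panel.cea if s.panel else float("nan") for s in timeline.samples]

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 7))
    for ax, y, label, cutoff in (
        (axes[0], vaf, "ctDNA VAF (%)", timeline.samples[0].call.cutoffs.lob if timeline.samples else None),
        (axes[1], cf, "cfDNA (ng/mL)", 5.6),
        (axes[2], cea, "CEA (ng/mL)", None),
    ):
        ax.plot(days, y, "o-", color="tab:purple")
        if cutoff is not None:
            ax.axhline(cutoff, color="grey", lw=0.8, ls=":")
        ax.set_ylabel(label)
        for e in timeline.events:
            color, ls = _EVENT_STYLE.get(e.kind.value, ("grey", ":"))
            ax.axvline(e.day, color=color, ls=ls, lw=0.8, alpha=0.7)
    axes[-1].set_xlabel("day")
    axes[0].set_title(f"{timeline.patient_id} ({timeline.assay_id}, UICC {timeline.uicc_stage})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
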