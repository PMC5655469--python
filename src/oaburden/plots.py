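"""A single diagnostic figure: per-person QALY loss by starting age band."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .burden import TOTAL
from .strata import GROUPS


def plot_loss_by_age(burden: pd.DataFrame, path: str | Path) -> Path:
    """Plot per-person QALY loss against age band, one line per group.

    The published pattern this visualises: losses fall with starting age
    because younger entrants have more quality-adjusted years left to lose.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    bands = burden[burden.age_band != TOTAL]
    for eth, sex in GROUPS:
        grp = bands[(bands.ethnicity == eth) & (bands.sex == sex)]
        label = f"{eth.replace('_', '-')} {sex}"
        ax.plot(grp.age_band, grp.per_person_loss, marker="o", label=label)
    ax.set_xlabel("age band at baseline")
    ax.set_ylabel("QALY loss per person with knee OA")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
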