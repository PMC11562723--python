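"""Quick-look plots for fields and fitted models (matplotlib optional)."""

from __future__ import annotations

import numpy as np

from .grid import Field


def plot_field(fld: Field, ax=None, cmap: str = "viridis", **imshow_kwargs):
    """Render a field as an image; missing cells are left transparent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = np.where(fld.missing, np.nan, fld.values)
    xmin, ymin, xmax, ymax = fld.grid.extent
    im = ax.imshow(vals, origin="lower", extent=(xmin, xmax, ymin, ymax),
                   cmap=cmap, **imshow_kwargs)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    title = fld.variable or "field"
    if fld.hour is not None:
        title += f" @ hour {fld.hour}"
    ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.85)
    return ax


def plot_importances(results, top: int = 15, ax=None):
    """Horizontal bar chart of impurity importances of a fitted model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    imp = results.importances.sort_values().tail(top)
    ax.barh(imp.index, imp.values)
    ax.set_xlabel("impurity importance")
    return ax
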