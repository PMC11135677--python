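"""Plain raster renders of intensity and CUTI surfaces (matplotlib)."""

from __future__ import annotations

import numpy as np

from .grid import Raster


def render_raster(raster: Raster, ax=None, cmap="viridis", title=None,
                  nodata_color="0.7"):
    """imshow a raster north-up; NaN cells shown in ``nodata_color``."""
    import matplotlib.pyplot as plt
    from matplotlib import colors

    if ax is None:
        _, ax = plt.subplots()
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(nodata_color)
    xmin, ymin, xmax, ymax = raster.grid.extent
    img = ax.imshow(np.ma.masked_invalid(raster.values[::-1]), cmap=cm,
                    extent=(xmin, xmax, ymin, ymax))
    ax.set_title(title or raster.name)
    ax.figure.colorbar(img, ax=ax, shrink=0.8)
    return ax
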