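"""Best-effort static rendering of the mobile at one time point.

Circle areas are proportional to the current transmitter weights; rods are
drawn at their computed rotation angles.  The drawing is illustrative, not
bit-specified.
"""

from __future__ import annotations

import math
from pathlib import Path

from .mobile import Leaf, MobileTree, Rod, rotation_angle, subtree_weight
from .transmitters import TransmitterProfile

__all__ = ["render_mobile"]

_DROP = 0.6  # vertical spacing between rod levels


def _draw(ax, node, x, y, profile, k_res, max_weight):
    if isinstance(node, Leaf):
        w = profile[node.transmitter]
        r = 0.18 * math.sqrt(w / max_weight)
        circle = __import__("matplotlib.patches", fromlist=["Circle"]).Circle(
            (x, y - r), r, fill=False, lw=1.2
        )
        ax.add_patch(circle)
        ax.text(x, y - 2 * r - 0.08, node.transmitter, ha="center", va="top", fontsize=8)
        return
    a = subtree_weight(node.left, profile)
    b = subtree_weight(node.right, profile)
    theta = rotation_angle(a, b, node.left_arm, node.right_arm, k_res)
    # positive theta: left end down (counterclockwise)
    lx = x - node.left_arm * math.cos(theta)
    ly = y - node.left_arm * math.sin(theta)
    rx = x + node.right_arm * math.cos(theta)
    ry = y + node.right_arm * math.sin(theta)
    ax.plot([lx, rx], [ly, ry], "k-", lw=1.5)
    ax.plot([x], [y], "k.", ms=3)
    for (cx, cy), child in (((lx, ly), node.left), ((rx, ry), node.right)):
        ax.plot([cx, cx], [cy, cy - _DROP], "k-", lw=0.8)
        _draw(ax, child, cx, cy - _DROP, profile, k_res, max_weight)


def render_mobile(
    tree: MobileTree,
    profile: TransmitterProfile,
    k_res: float,
    path: str | Path,
    *,
    title: str | None = None,
) -> Path:
    """Render the mobile under the given weights to a vector graphic (SVG/PDF)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    max_weight = max(profile.values)
    ax.plot([0, 0], [0.5, 0], "k-", lw=0.8)
    _draw(ax, tree.root, 0.0, 0.0, profile, k_res, max_weight)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path
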