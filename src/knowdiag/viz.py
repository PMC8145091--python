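"""Static HTML rendering of attention weights.

Two interpretability artifacts: a hierarchical heatmap of the document
encoder (red line shading = sentence attention, blue token shading = word
attention, darker = larger, each level min-max normalized across the
document) and a knowledge-attention table (one row per concept whose weight
clears the display cutoff, default 1e-3, intensity proportional to the
weight).

The HTML is self-contained (inline CSS, no scripts) and embeds the
normalized weights as ``data-weight`` attributes so they can be recovered
programmatically from the rendered file.
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoder import EncodedDoc
from .knowledge import AggregatedKnowledge

__all__ = ["render_document_attention", "render_knowledge_attention"]

KNOWLEDGE_CUTOFF_DEFAULT = 1e-3

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
.sentence {{ padding: 0.2em 0.4em; margin: 0.15em 0; border-radius: 4px; }}
.token {{ padding: 0 0.15em; border-radius: 2px; }}
.concept {{ padding: 0.3em 0.5em; margin: 0.2em 0; border-radius: 4px; }}
</style></head><body>
<h2>{title}</h2>
{body}
</body></html>
"""


def _minmax(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalize over masked-in entries; constant input maps to 0.5."""
    out = np.zeros_like(values, dtype=float)
    vals = values[mask]
    if vals.size == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    out[mask] = 0.5 if hi - lo < 1e-12 else (values[mask] - lo) / (hi - lo)
    return out


def render_document_attention(
    encoded: EncodedDoc,
    tokens: Sequence[Sequence[str]],
    out: str | Path,
    mode: str = "plain",
) -> str:
    """Write the hierarchical attention heatmap for one document.

    ``tokens`` is the document's sentence/word structure (pre-padding).  In
    ``sentence_scaled`` mode word intensities are multiplied by their
    sentence's normalized weight, emphasizing words in important sentences.
    """
    if not tokens or all(len(s) == 0 for s in tokens):
        raise ValueError("cannot render an empty document")
    L = min(len(tokens), encoded.sentence_attention.shape[0])
    sent_mask = np.zeros_like(encoded.sentence_attention, dtype=bool)
    sent_mask[:L] = True
    sent_norm = _minmax(encoded.sentence_attention, sent_mask)

    word_mask = np.zeros_like(encoded.word_attention, dtype=bool)
    for i in range(L):
        word_mask[i, : min(len(tokens[i]), word_mask.shape[1])] = True
    word_norm = _minmax(encoded.word_attention, word_mask)
    if mode == "sentence_scaled":
        word_norm = word_norm * sent_norm[:, None]
    elif mode != "plain":
        raise ValueError(f"unknown rendering mode {mode!r}")

    lines = []
    for i in range(L):
        sw = sent_norm[i]
        spans = []
        for t, tok in enumerate(tokens[i][: word_mask.shape[1]]):
            ww = word_norm[i, t]
            spans.append(
                f'<span class="token" data-weight="{ww:.6f}" '
                f'style="background: rgba(0,0,255,{0.75 * ww:.4f})">'
                f"{html.escape(tok)}</span>"
            )
        lines.append(
            f'<div class="sentence" data-weight="{sw:.6f}" '
            f'style="background: rgba(255,0,0,{0.45 * sw:.4f})">'
            + " ".join(spans) + "</div>"
        )
    page = _PAGE.format(title="Document attention", body="\n".join(lines))
    Path(out).write_text(page, encoding="utf-8")
    return page


def render_knowledge_attention(
    aggregated: AggregatedKnowledge,
    out: str | Path,
    cutoff: float = KNOWLEDGE_CUTOFF_DEFAULT,
) -> str:
    """Write the knowledge-attention table; weights below cutoff are omitted."""
    rows = sorted(
        ((cid, w) for cid, w in aggregated.attention.items() if w >= cutoff),
        key=lambda kv: (-kv[1], kv[0]),
    )
    max_w = rows[0][1] if rows else 1.0
    body = []
    for cid, w in rows:
        intensity = w / max_w if max_w > 0 else 0.0
        mark = " &#9733;" if cid in aggregated.selected else ""
        body.append(
            f'<div class="concept" data-weight="{w:.6f}" '
            f'style="background: rgba(0,128,0,{0.6 * intensity:.4f})">'
            f"{html.escape(cid)} &mdash; attention {w:.4f}{mark}</div>"
        )
    if not body:
        body.append("<p>No knowledge document cleared the display cutoff.</p>")
    page = _PAGE.format(title="Knowledge attention", body="\n".join(body))
    Path(out).write_text(page, encoding="utf-8")
    return page
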