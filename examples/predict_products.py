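"""Predict post-editing translational products and epitope loss.

Takes the classic APP C-terminus frameshift allele (a 5-bp deletion at
the cut site) and predicts the resulting protein: how far translation
proceeds along the wildtype sequence, which novel residues the shifted
frame appends before the premature stop, and whether the C-terminal
antibody epitope (Y188, the last 20 residues) survives.
"""

from ampedit import VariantSignature, predict_product, epitope_retention
from ampedit.align_core import VariantOp
from ampedit.app_synthetic import (
    APP659_GG_DELETION,
    APP_CODING_MAP,
    Y188_EPITOPE,
    app_cterm_cds,
)

ctx = app_cterm_cds("human").seq

for label, sig in [
    ("unedited", VariantSignature()),
    ("5-bp deletion at cut", APP659_GG_DELETION),
    ("1-bp deletion at cut", VariantSignature((VariantOp("deletion", 61, 1),))),
]:
    product = predict_product(ctx, sig, APP_CODING_MAP, "APP")
    retained = epitope_retention(product, [Y188_EPITOPE])["Y188"]
    print(f"{label:22s} -> {product.name:14s} "
          f"last WT residue {product.last_wt_residue}, "
          f"{product.truncated_count} aa truncated, "
          f"appended {product.appended or '-'}, "
          f"Y188 retained {retained:.2f}")

print(
    "\nA frameshift at the codon-659/660 boundary of the 695-residue protein "
    "truncates the\nlast 36 residues, so the Y188 epitope (676-695) is lost "
    "entirely (retention 0.00).\nThe 5-bp deletion's shifted frame appends "
    "Gly-Gly before stopping: product APP-659-GG."
)
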