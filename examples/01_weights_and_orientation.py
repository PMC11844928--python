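"""Build score weights from an EWAS catalog, transforming orientation.

Constructs a tiny weight catalog containing both orientations, selects the
usable CpGs, and finalizes the external weights.  For CpGs whose source EWAS
modeled methylation as the *dependent* variable, the reported coefficient is
converted with R² = Z²/(Z²+N−1), β* = β(1−R²)/((N−1)·SE²) so that every
final weight measures trait change per unit methylation.
"""

import pegskit as pk

records = [
    # trait-on-methylation EWAS: coefficient already points the right way
    pk.EWASWeightRecord("cg0001", beta=0.85, se=0.12, n=15_000,
                        orientation="meth_independent"),
    # methylation-on-trait EWAS: needs the orientation transformation
    pk.EWASWeightRecord("cg0002", beta=0.0021, se=0.0003, n=15_000,
                        orientation="meth_dependent"),
    # significant in the EWAS but not measured on our array
    pk.EWASWeightRecord("cg9999", beta=0.40, se=0.05, n=15_000,
                        orientation="meth_independent"),
    # not Bonferroni-significant: excluded by the selection rule
    pk.EWASWeightRecord("cg0003", beta=0.10, se=0.08, n=15_000,
                        orientation="meth_independent",
                        bonferroni_significant=False),
]

available = {"cg0001", "cg0002", "cg0003"}  # probes on the array
selected = pk.select_cpgs(records, available)
final = pk.finalize_weights(selected)

print(f"{len(records)} catalog rows -> {len(final)} usable weights\n")
for rec, tw in zip(selected, final):
    print(f"{tw.cpg_id}: reported beta={rec.beta:9.4f} ({rec.orientation})"
          f"  R2={tw.r2:.4f}  final weight={tw.w:9.4f}")

# The meth_independent weight passes through unchanged; the meth_dependent
# coefficient (0.0021 beta-value per trait unit) becomes a large weight in
# trait units per beta-value, matching the slope of the reverse regression.
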