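"""Score a prediction against a reference delineation.

Generates a protein with a disordered N-terminus, segments it, and prints
the two evaluation scores: IoU (overlap of matched domain residue sets;
1 = perfect) and DBD (per-boundary 1 minus 1/8 per residue of displacement,
averaged over the accuracy and sensitivity directions).  The permissibility
curve shows the fraction of predicted boundaries within 0..7 residues of a
reference boundary.
"""

from paeseg import (
    Architecture,
    Element,
    evaluate,
    format_chopping,
    generate_pae,
    segment_pae,
)

arch = Architecture(
    (Element("disordered_n", 40), Element("domain", 200), Element("linker", 10),
     Element("domain", 90)),
    rng_seed=21,
)
pae, truth = generate_pae(arch, noise_sd=0.5)
pred = segment_pae(pae)
report = evaluate(pred, truth)

print(f"reference : {format_chopping(truth)}")
print(f"predicted : {format_chopping(pred)}")
print(f"IoU  = {report.iou:.4f}")
print(f"DBD  = {report.dbd:.4f}")
print("accuracy over permissibility distances 0..7:",
      " ".join(f"{report.accuracy_at[x]:.2f}" for x in sorted(report.accuracy_at)))
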