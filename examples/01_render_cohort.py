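"""Generate a synthetic SPSN cohort: nodule patches plus the clinical table.

Prints the class-conditional summary of the generated covariates; the
directions mirror the emulated study population (adenocarcinomas are
older, larger, more often lobulated/spiculated and more often women).
"""

from tlradiomics.fixtures import SyntheticCohortSpec, generate_target_cohort

spec = SyntheticCohortSpec(n=300, patch_size=64, seed=1)
patches, table = generate_target_cohort(spec)

print(f"{len(patches)} patches of {patches[0].size}x{patches[0].size} px")
print(f"prevalence of adenocarcinoma: {table['label'].mean():.3f}\n")
for label, name in ((0, "granuloma (LGN)"), (1, "adenocarcinoma (LAC)")):
    grp = table[table.label == label]
    print(
        f"{name:22s} age {grp['age'].mean():5.1f} y | "
        f"size {grp['nodule_size'].mean():5.1f} mm | "
        f"lobulated {(grp['lobulated'] == 'presence').mean():.2f} | "
        f"spiculated {(grp['spiculated'] == 'presence').mean():.2f} | "
        f"women {(grp['gender'] == 'women').mean():.2f}"
    )
print(
    "\nEach row is one synthetic patient; the image patch encodes the same "
    "morphology (size, lobulation, spiculation, margin) that the table records."
)
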