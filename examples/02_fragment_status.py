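"""Fragment-level status: does a chain segment support the core?

RD_FR repeats the RD computation on a renormalized contiguous slice of
the O and T profiles.  A fragment with RD_FR < 0.5 locally follows the
micelle-like field; RD_FR > 0.5 marks local discordance — the statistic
used to compare chameleon sequences across proteins.
"""

from fodm import FragmentSpec, analyze_fragment, analyze_unit
from fodm.fixtures import FixtureSpec, generate

fx = generate(FixtureSpec(mode="micelle", n_residues=60, seed=0))
ua = analyze_unit(fx.eas, hydrophobicity=fx.hydrophobicity)

print(f"unit RD        {ua.result.rd:.3f}")
whole = analyze_fragment(ua, FragmentSpec(0, 60))
print(f"RD_FR[0,60)    {whole.rd_fr:.3f}   (whole chain: equals unit RD)")

for start, end in [(0, 10), (25, 35), (50, 60)]:
    fa = analyze_fragment(ua, FragmentSpec(start, end))
    verdict = "supports core" if fa.rd_fr < 0.5 else "locally discordant"
    print(f"RD_FR[{start:2d},{end:2d})   {fa.rd_fr:.3f}   {verdict}")

print()
print("Each fragment's O and T slices are renormalized to sum 1 before")
print("comparison, so short segments are judged on profile shape, not on")
print("how much total hydrophobicity they carry.")
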