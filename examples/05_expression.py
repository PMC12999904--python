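"""FPKM normalisation, the fold-change screen and 2^-ddCt qPCR analysis."""

from asterfam import ddct, de_screen, fpkm
from asterfam.expression import QpcrRecord

f_treated = fpkm(count=480, transcript_length_bp=1600, total_mapped=1_000_000)
f_control = fpkm(count=100, transcript_length_bp=1600, total_mapped=1_000_000)
call = de_screen(f_treated, f_control, gene_id="gene1")
print(f"FPKM treated {f_treated:.1f}, control {f_control:.1f}; "
      f"log2FC = {call.log2fc:.3f}, responsive = {call.responsive}")

control = [QpcrRecord("gene1", "salt", 0, r, 25.0, 20.0) for r in (1, 2, 3)]
treated = [QpcrRecord("gene1", "salt", 6, r, 22.0, 20.0) for r in (1, 2, 3)]
res = ddct(treated, control)
print(f"2^-ddCt at 6 h: fold = {res.mean_fold:.2f} +/- {res.sd_fold:.2f}")
# dCt drops from 5 to 2 cycles, i.e. 2^3 = 8-fold induction relative to
# the 0 h control; |log2FC| > 1 marks the gene stress-responsive.
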