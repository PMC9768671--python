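# Full pipeline run: simulate -> per-cell fits -> shifts -> permutation -> QC
seed: 123
n_cells: 12
noise_sd: 0.02
n_perm: 10000
reference: ASIC3-WT
conditions: [80nM, 2mM]
constructs:
  - name: ASIC3-WT
  - name: E435A          # pore-entry mutant: reduced low-Ca2+ shift
    ph50_80nm: 6.91
    sd_80nm: 0.24
  - name: E212A          # acidic-pocket mutant
    ph50_80nm: 6.98
    sd_80nm: 0.26
outdir: asicca_run
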