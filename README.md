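# gtctopo

Membrane topology and luminal-motif analysis for multi-pass ER
glycosyltransferases (GT-C superfamily).

Polytopic ER glycosyltransferases share a recognizable architecture: 11–14
transmembrane helices, a cytoplasmic N-terminus, large luminal loops that
carry the conserved catalytic motifs, and — in some families — a C-terminal
dilysine ER-retrieval signal. `gtctopo` assigns that architecture to a
family alignment:

* **seqio** — FASTA/Stockholm/Clustal alignment I/O, reference-coordinate
  mapping (degapping to a designated human reference), greedy maximin
  selection of diverse homolog subsets;
* **topology** — consensus Kyte–Doolittle hydropathy profiling, TM-helix
  segmentation (with splitting of over-long hydrophobic runs and raw-profile
  boundary refinement), orientation by the positive-inside rule with a
  dilysine override;
* **conservation** — per-position information content in bits,
  conserved-position calling, sequence-logo matrix export;
* **motifs** — a PROSITE-like degenerate pattern grammar, exhaustive
  scanning, loop assignment, and a curated GT-C motif library plus family
  registry;
* **model** — the family report: organization string (`1-8-4`, `1-6-4`,
  `1-6-5`, `1-6-7`), motif–loop concordance checks, and a permutation test
  for luminal-vs-cytoplasmic conservation asymmetry;
* **massspec** — tryptic digestion and monoisotopic m/z of C-mannosylated
  (hexose-modified) glycopeptides;
* **synth** — synthetic families with known ground truth for end-to-end
  validation.

See `docs/methods.md` for algorithmic details and design rationale.

## Worked example

Generate a synthetic 13-helix family (the STT3-like architecture) and run
the full pipeline on it:

```sh
# 25 aligned sequences + ground truth
gtctopo simulate --n-tmds 13 --seed 7 --out sim/

# profile -> segmentation -> orientation -> conservation -> motifs -> report
gtctopo run-family \
    --alignment sim/family.fasta --reference ref --family STT3 \
    --seed 0 --out run/
```

`run/report.json` then contains, among other fields:

```json
{
  "organization": "1-8-4",
  "n_tmds": 13,
  "n_term_side": "cytoplasmic",
  "asymmetry": {"statistic": 0.75, "p_value": 0.001, "n_perm": 1000}
}
```

i.e. thirteen helices partitioned 1–8–4 by the two large luminal loops, a
cytoplasmic N-terminus by the positive-inside rule, and significantly
higher conservation in luminal than cytoplasmic loops. Alongside the
report, `run/` holds the hydropathy profile (`profile.tsv`), helix
coordinates (`segments.tsv`, BED-like), the logo matrix (`logo.tsv`) and
motif hits (`hits.tsv`).

Glycopeptide ions — the m/z ladder of a C-mannosylated tryptic peptide at
charge 3, with cysteines carbamidomethylated:

```sh
$ gtctopo run-mz LDGGWSSWSDWSACSSSCHR --max-hex 2 --charge 3
hexoses  z  mass       mz
0        3  2326.9120  776.6446
1        3  2488.9648  830.6622
2        3  2651.0177  884.6798
```

Diverse-subset selection from a (aligned) FASTA:

```sh
gtctopo select-diverse homologs.fasta -k 25
```

The same functionality is available as a library:

```python
from gtctopo import conservation, model, synth, topology

fam, truth = synth.generate(synth.default_spec(13, seed=7))
profile, topo = topology.predict_topology(fam)
prof = conservation.conservation_profile(fam)
result = model.asymmetry_test(topo, prof, n_perm=1000, seed=0)
print(topo.n_tmds, model.organization_string(topo), result.p_value)
```

## Testing

```sh
pip install --no-build-isolation -e .[test]
pytest -q
```

`tests/test_acceptance.py` holds the five end-to-end acceptance checks
(glycopeptide ions, organization classification, noise-free topology
recovery, asymmetry-test power and calibration, oracle equivalences);
`scripts/acceptance.py --seed 1 --out results/acceptance.json` writes the
three reference ion values as JSON.
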