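# Deposited crystal structures (user-supplied)

The structure-based acceptance checks measure the deposited UBR-box
coordinates, which are not redistributable inside this repository.
To run them, download the entries into this directory (keeping the
accession code as the file name, `.cif` or `.pdb`):

```sh
curl -O https://files.rcsb.org/download/8J9Q.cif   # apo UBR4 UBR box
curl -O https://files.rcsb.org/download/8J9R.cif   # YIFS-bound UBR4 UBR box
# optional, for the subfamily divergence-ordering comparison:
curl -O https://files.rcsb.org/download/3NIH.cif   # yeast UBR1 UBR box
curl -O https://files.rcsb.org/download/3NY3.cif   # human UBR2 UBR box
```

Everything else in the test suite and the acceptance script is
synthetic and needs no downloads.
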