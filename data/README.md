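# External verification data (user-supplied, never bundled)

Some verification targets check published counts on the public
*Bacillus subtilis* 168 *argF* coding sequence (locus BSU11250 on
NC_000964.3; the encoded protein is UniProt P18186 / OTC_BACSU, 319 aa).
Download the CDS nucleotide FASTA yourself and save it here as
`argF_bsu168.fna` (single record, CDS only, ATG through the stop codon,
~960 nt). For example, with NCBI E-utilities:

```sh
curl -s 'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=NC_000964.3&rettype=fasta_cds_na&retmode=text' \
  | awk '/^>/{keep=/argF/} keep' > argF_all_header.fna
# then keep the single argF record and simplify its header, e.g.:
seqkit seq argF_all_header.fna | seqkit head -n 1 | sed '1s/.*/>argF_bsu168/' > argF_bsu168.fna
```

With the file in place, `tests/test_acceptance.py::TestCriterion2ArgF` and
the t1/t3/t4 entries of `scripts/acceptance.py` become active.
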