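{
 "schema_version": 1,
 "_comment": [
  "Wavefunction container, JSON flavour (schema version 1).",
  "basis: one spatial-orbital set; spin orbitals are indexed alpha block",
  "(0 .. n_spatial-1) then beta block (n_spatial .. 2*n_spatial-1).",
  "states/<label>/terms: [[occupied spin orbitals (ascending)], coefficient].",
  "states/<label>/csf_terms: CSF input instead of determinants, entries",
  "[[spatial_occ [[orbital, occupancy]...], coupling vector, M_S], coeff];",
  "CSFs use genealogical coupling (+1/-1 spin steps over the singly",
  "occupied orbitals in ascending order) and are expanded on load with the",
  "stated screening thresholds (csf_threshold defaults to 1e-4, strict).",
  "Energies in eV. The same layout maps onto HDF5 groups /basis and",
  "/states/<label> for determinant-based states."
 ],
 "basis": {"mo_set_id": "toy-neutral", "n_spatial": 3},
 "states": {
  "S0": {
   "n_electrons": 4,
   "multiplicity": 1,
   "energy": 0.0,
   "terms": [
    [[0, 1, 3, 4], 0.98],
    [[0, 2, 3, 5], -0.19899748742132396]
   ]
  },
  "S1": {
   "multiplicity": 1,
   "energy": 4.6,
   "csf_terms": [
    [[[[0, 2], [1, 1], [2, 1]], [1, -1], 0.0], 1.0]
   ],
   "csf_threshold": 1e-4
  }
 }
}
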