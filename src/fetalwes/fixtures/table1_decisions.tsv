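# Review decisions for the 52 diagnostic findings: the published
# table does not print the pathogenic / likely-pathogenic tier per
# row, so each is recorded at the tier-agnostic 'pathogenic' value
# with full causal contribution.
diagnosis_id	classification	contribution	clinically_relevant_vus
PP0087	pathogenic	full	false
PP0174	pathogenic	full	false
PP0184	pathogenic	full	false
PP0204	pathogenic	full	false
PP0258	pathogenic	full	false
PP0318	pathogenic	full	false
PP0333	pathogenic	full	false
PP0342	pathogenic	full	false
PP0384	pathogenic	full	false
PP0390	pathogenic	full	false
PP0513	pathogenic	full	false
PP0555	pathogenic	full	false
PP0602	pathogenic	full	false
PP0656	pathogenic	full	false
PP0659	pathogenic	full	false
PP0792	pathogenic	full	false
PP0981	pathogenic	full	false
PP1408	pathogenic	full	false
PP1462	pathogenic	full	false
PP1561	pathogenic	full	false
PP1573	pathogenic	full	false
PP1579	pathogenic	full	false
PP1627	pathogenic	full	false
PP1711	pathogenic	full	false
PP1726	pathogenic	full	false
PP1750	pathogenic	full	false
PP1753	pathogenic	full	false
PP1780	pathogenic	full	false
PP1795	pathogenic	full	false
PP1807	pathogenic	full	false
PP1843	pathogenic	full	false
PP1864	pathogenic	full	false
PP1892	pathogenic	full	false
PP1934	pathogenic	full	false
PP1967	pathogenic	full	false
PP2000	pathogenic	full	false
PP2009	pathogenic	full	false
PP2015	pathogenic	full	false
PP2033	pathogenic	full	false
PP2039	pathogenic	full	false
PP2141	pathogenic	full	false
PP2645	pathogenic	full	false
PP2718	pathogenic	full	false
PP2904	pathogenic	full	false
PP2979	pathogenic	full	false
PP3168	pathogenic	full	false
PP3246	pathogenic	full	false
PP3387	pathogenic	full	false
PP3540	pathogenic	full	false
PP0626	pathogenic	full	false
PP2567	pathogenic	full	false
PP0503	pathogenic	full	false
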