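{
  "version": 1,
  "comment": "One record per host-survey row (museum lot or fresh collection). worm_counts lists worms per infected host where the per-host distribution is fixed by the infection-parameters account; where only a range or a pooled figure is given, worm_counts is null and n_infected / reported_mean_intensity carry what was stated.",
  "surveys": [
    {"row_id": 1, "host": "Limnothrissa miodon", "locality": "Lake Itezhi-Tezhi", "country": "Zambia", "n_examined": 24, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 2, "host": "Microthrissa congica", "locality": "Manyanga", "country": "DRC", "n_examined": 9, "worm_counts": [1, 1], "parasite": "Kapentagyrus bisthoveni", "notes": ["infection account spells the locality 'Manianga' and counts eight hosts; table row (n = 9) kept canonical"]},
    {"row_id": 3, "host": "Microthrissa congica", "locality": "Poko", "country": "DRC", "n_examined": 2, "worm_counts": [2], "parasite": "Kapentagyrus bisthoveni", "notes": []},
    {"row_id": 4, "host": "Microthrissa congica", "locality": "Mobi River", "country": "DRC", "n_examined": 2, "worm_counts": [1], "parasite": "Kapentagyrus bisthoveni", "notes": []},
    {"row_id": 5, "host": "Microthrissa congica", "locality": "Inkongo, Sankuru River", "country": "DRC", "n_examined": 1, "worm_counts": [], "parasite": null, "notes": ["single specimen not infected"]},
    {"row_id": 6, "host": "Microthrissa congica", "locality": "Kinshasa", "country": "DRC", "n_examined": 3, "worm_counts": [], "parasite": null, "notes": ["Atena Island; none of three hosts infected"]},
    {"row_id": 7, "host": "Microthrissa congica", "locality": "Lualaba River", "country": "DRC", "n_examined": 12, "worm_counts": [1, 1, 1], "parasite": "Kapentagyrus boegeri", "notes": []},
    {"row_id": 8, "host": "Microthrissa moeruensis", "locality": "Lake Mweru", "country": "Zambia", "n_examined": 11, "worm_counts": [1, 1, 1], "parasite": "Kapentagyrus chochamandai", "notes": ["infection account says three out of ten; table row (n = 11) kept canonical"]},
    {"row_id": 9, "host": "Microthrissa moeruensis", "locality": "Kashilu", "country": "Zambia", "n_examined": 5, "worm_counts": [1, 1], "parasite": "Kapentagyrus chochamandai", "notes": []},
    {"row_id": 10, "host": "Microthrissa royauxi", "locality": "Pool Malebo", "country": "DRC", "n_examined": 11, "worm_counts": [1, 1, 1, 1, 1, 2, 2, 2], "parasite": "Kapentagyrus rochetteae", "notes": ["infection account pools the two Pool Malebo lots (8/13 infected, 11 worms, intensity 1.4); counts attached to the symbiotype lot", "one or two worms per infected host with 11 worms over 8 hosts fixes five singles and three doubles"]},
    {"row_id": 11, "host": "Microthrissa royauxi", "locality": "Pool Malebo", "country": "DRC", "n_examined": 2, "worm_counts": [], "parasite": "Kapentagyrus rochetteae", "notes": ["counts pooled into row 10"]},
    {"row_id": 12, "host": "Nannothrissa parva", "locality": "Lake Tumba", "country": "DRC", "n_examined": 9, "worm_counts": [1, 2], "parasite": "Kapentagyrus parisellei", "notes": []},
    {"row_id": 13, "host": "Nannothrissa parva", "locality": "Lake Tumba", "country": "DRC", "n_examined": 10, "worm_counts": null, "n_infected": 6, "parasite": "Kapentagyrus parisellei", "notes": ["tributary of Lake Tumba; one or two worms per infected host, total unresolved"]},
    {"row_id": 14, "host": "Nannothrissa parva", "locality": "Mbandaka", "country": "DRC", "n_examined": 2, "worm_counts": [], "parasite": null, "notes": ["then known as Coquilhatville; none of two hosts infected"]},
    {"row_id": 15, "host": "Odaxothrissa mento", "locality": "Lake Volta", "country": "Ghana", "n_examined": 2, "worm_counts": [1], "parasite": "Kapentagyrus marispastoris", "notes": ["infection account pools the two Lake Volta lots (1/3 infected); count attached to the symbiotype lot"]},
    {"row_id": 16, "host": "Odaxothrissa mento", "locality": "Lake Volta", "country": "Ghana", "n_examined": 1, "worm_counts": [], "parasite": "Kapentagyrus marispastoris", "notes": ["counts pooled into row 15"]},
    {"row_id": 17, "host": "Odaxothrissa ansorgii", "locality": "Lake Nguene", "country": "Gabon", "n_examined": 10, "worm_counts": null, "n_infected": 4, "reported_mean_intensity": 2.0, "parasite": "Kapentagyrus voreli", "notes": ["one to three worms per infected host; only the mean intensity was reported"]},
    {"row_id": 18, "host": "Odaxothrissa ansorgii", "locality": "Aboun, Noya River", "country": "Gabon", "n_examined": 2, "worm_counts": [1], "parasite": "Kapentagyrus voreli", "notes": ["the infection account spells the locality 'Aboumé'"]},
    {"row_id": 19, "host": "Odaxothrissa losera", "locality": "Pool Malebo", "country": "DRC", "n_examined": 2, "worm_counts": [3, 16], "parasite": "Kapentagyrus sefcae", "notes": []},
    {"row_id": 20, "host": "Potamothrissa acutirostris", "locality": "Ankoro", "country": "DRC", "n_examined": 2, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 21, "host": "Potamothrissa acutirostris", "locality": "Kilwa, Lake Mweru", "country": "DRC", "n_examined": 10, "worm_counts": [1], "parasite": "Kapentagyrus chochamandai", "notes": []},
    {"row_id": 22, "host": "Potamothrissa acutirostris", "locality": "Tshopo River", "country": "DRC", "n_examined": 2, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 23, "host": "Potamothrissa acutirostris", "locality": "Bosabangi", "country": "DRC", "n_examined": 1, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 24, "host": "Potamothrissa obtusirostris", "locality": "Kindu, Lualaba River", "country": "DRC", "n_examined": 1, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 25, "host": "Potamothrissa obtusirostris", "locality": "Oso River", "country": "DRC", "n_examined": 1, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 26, "host": "Pellonula leonensis", "locality": "Agorkpo Creek", "country": "Ghana", "n_examined": 7, "worm_counts": [1, 1, 2], "parasite": "Kapentagyrus hahni", "notes": ["one or two worms per infected host with printed intensity 1.3 fixes two singles and one double"]},
    {"row_id": 27, "host": "Pellonula leonensis", "locality": "Lake Volta", "country": "Ghana", "n_examined": 19, "worm_counts": null, "n_infected": 13, "parasite": "Kapentagyrus hugei", "notes": ["one to nine worms per infected host; total unresolved"]},
    {"row_id": 28, "host": "Pellonula leonensis", "locality": "Lambaréné", "country": "Gabon", "n_examined": 6, "worm_counts": [2, 3], "parasite": "Kapentagyrus verbisti", "notes": ["survey table misprints the country as Ghana; Lambaréné is in Gabon"]},
    {"row_id": 29, "host": "Pellonula vorax", "locality": "Lake Nguene", "country": "Gabon", "n_examined": 2, "worm_counts": [], "parasite": null, "notes": ["screened without success"]},
    {"row_id": 30, "host": "Pellonula vorax", "locality": "Lake Nguene", "country": "Gabon", "n_examined": 1, "worm_counts": [], "parasite": null, "notes": ["screened without success"]}
  ]
}
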