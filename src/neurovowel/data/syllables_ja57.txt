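# Imagined-speech protocol: 57 Japanese short syllables (CV grid).
# "-" marks an empty cell.  Vowel of a syllable = its final romaji letter.
# vowels: i e a o u
# repetitions: i=50 e=50 a=65 o=60 u=60
# subjects: 5
a	ka	sa	ta	na	ha	ma	ya	ra	wa	ga	za	kya
i	ki	shi	chi	ni	hi	mi	-	ri	-	gi	zi	-
u	ku	su	tsu	nu	hu	mu	yu	ru	-	gu	zu	kyu
e	ke	se	te	ne	he	me	-	re	-	ge	ze	-
o	ko	so	to	no	ho	mo	yo	ro	-	go	zo	kyo
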