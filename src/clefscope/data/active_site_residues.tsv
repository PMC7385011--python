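seq_id	organism	residues
Q5NAT0	Oryza sativa	L60, Q64, A67, A75, K78, A79, S172, V417, Y423, R425, S442, F443, G459, P461, L463, D465, S520, L521, Q522, L532, W554, Y561, R563, Y590, V593, V605, P607, W609
Q8LJP6	Gossypium hirsutum	L47, Q51, T54, A57, N62, D80, V82, F84, T157, N159, T223, V224, Q226, Y227, Y228, R414, A436, W437, Y469, Y496, Q498, L499, L500, V503, T504, L512, P513, K514, A516, I538, V542, T543, Y544, I550, N561, K563, L569, Y570, S587, W588, I589, S597, M598
Q93WY9	Nicotiana tabacum	L67, Y142, T149, T150, Y153, W155, T162, Y233, Y440, T442, W443, F444, P451, V508, A509, I510, P511, P513, K514, V521, T522, P525, Q536, K547, T548, Y550, M464, L567, K568, L569, Y572, K583, Y584
Q9ZSP9	Solanum lycopersicum	Y43, N47, R49, N55, L58, K62, S106, D139, N141, T142, Y145, W435, S437, D451, P502, P504, T507, K509, A511, P512, K515, P520, R521, P522, R523, V524, L525, P526, T534, L545, T549, Y550, Y551, R552, Y553, L575, P578, L579, F591, L595, N596, V607, V619
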