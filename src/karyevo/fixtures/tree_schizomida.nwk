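(Outgroup,(Agastoschizomus_lucifer,((Orientzomus_Luzon,Orientzomus_Mindanao),(Clavizomus_sp,((Notozomus_sp,Hubbardiidae_Seychelles),((Rowlandius_ubajara,Rowlandius_sp),(Stenochrus_sp,(Olmecazomus_brujo,Hubbardiidae_Cameroon))))))));
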