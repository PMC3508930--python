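population,mpg,caste_tribe,rank,district
Paniya,HTF,Tribe,TR,Nilgiris
Paliyan,HTF,Tribe,TR,Theni
Pulayar,HTF,Tribe,TR,Coimbatore
Irula,HTF,Tribe,TR,Nilgiris
Kadar,HTF,Tribe,TR,Coimbatore
Kanikaran,HTC,Tribe,TR,Tirunelveli
Thoda,HTC,Tribe,TR,Nilgiris
Kota,HTC,Tribe,TR,Nilgiris
Betta Kurumba,HTK,Tribe,TR,Nilgiris
Kattunaickan,HTK,Tribe,TR,Nilgiris
Kurumba,HTK,Tribe,TR,Nilgiris
Mullukurumba,HTK,Tribe,TR,Nilgiris
Parayar NTN,SC,Caste,LOW,N.Arcot
Parayar,SC,Caste,LOW,Madurai
Pallar,SC,Caste,LOW,Tirunelveli
Paravar,SC,Caste,LOW,Trichendur
Yadhava,DLF,Caste,MID,Madurai
Vanniyar,DLF,Caste,MID,Erode
Vanniyar NTN,DLF,Caste,MID,N.Arcot
Nadar TNV,DLF,Caste,MID,Tirunelveli
Nadar Cape,DLF,Caste,MID,Kanyakumari
Piramalai Kallar,DLF,Caste,MID,Madurai
Maravar,DLF,Caste,MID,Ramnad
Valayar,AW,Caste,LOW,Madurai
Tamil Jains,AW,Caste,MID,N.Arcot
Ezhava,AW,Caste,MID,Kanyakumari
Mukkuvar,AW,Caste,LOW,Kanyakumari
Sourashtra,BRH,Caste,MID,Madurai
Brahacharanam,BRH,Caste,HIGH,Tirunelveli
Iyengar,BRH,Caste,HIGH,Madurai
Vadama,BRH,Caste,HIGH,Tirunelveli
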